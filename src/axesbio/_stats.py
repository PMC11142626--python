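"""Statistical kernels used across the package.

Thin, explicitly-named wrappers over scipy/statsmodels so every module
draws its correlations, rank tests, enrichment tails and FDR control
from one audited surface.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["pearson", "spearman", "mann_whitney_u", "hypergeom_tail",
           "bh_adjust"]


def pearson(x, y) -> tuple[float, float]:
    """Pearson correlation coefficient and two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance input")
    r = stats.pearsonr(x, y)
    return float(r.statistic), float(r.pvalue)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation and two-sided p-value."""
    r = stats.spearmanr(x, y)
    return float(r.statistic), float(r.pvalue)


def mann_whitney_u(x, y, alternative: str = "greater") -> tuple[float, float]:
    """Mann-Whitney U statistic of ``x`` vs ``y`` and its p-value.

    ``alternative='greater'`` tests whether values in ``x`` tend to
    exceed those in ``y`` (one-tailed).
    """
    res = stats.mannwhitneyu(x, y, alternative=alternative)
    return float(res.statistic), float(res.pvalue)


def hypergeom_tail(overlap: int, pop: int, successes: int, draws: int) -> float:
    """P(X >= overlap) for a hypergeometric draw.

    ``pop`` genes total, ``successes`` of them carry the annotation,
    ``draws`` genes in the cluster, ``overlap`` annotated genes observed
    in the cluster.
    """
    return float(stats.hypergeom.sf(overlap - 1, pop, successes, draws))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values for a flat array."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p.ravel(), method="fdr_bh")[1].reshape(p.shape)
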