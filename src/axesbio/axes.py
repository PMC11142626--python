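"""Associating annotations and genes with the axes of an embedding space.

Given the basis ``B`` (n x d, columns = axes) of a gene embedding space
and a binary term x gene annotation matrix ``M``, the annotations are
embedded into the same space by least squares,

    M ~= U B^T   =>   U = M pinv(B^T),

so row ``u_i`` of ``U`` holds the coordinates of annotation ``a_i`` on
the axes.  An annotation is *associated* with axis ``j`` when its
coordinate ``u_i[j]`` is (a) significantly larger than expected under a
permutation null that shuffles the gene columns of ``M``, with
empirical p-value (c+1)/(n_perm+1) and per-annotation Benjamini-Hochberg
control across the d axes, and (b) the maximum entry of ``u_i`` (hard
clustering: each annotation lands on at most one axis).  Genes are
assigned to the axis on which their embedding vector projects highest.

The :class:`AxisAnnotator` model wraps this procedure;
:func:`dimensionality_scan` repeats it over a grid of dimensionalities
and picks the smallest one on the capture plateau.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._stats import bh_adjust
from .annotations import AnnotationTable
from .nmtf import NMTF, NMTFResults

__all__ = ["AxisAnnotator", "AxisAnnotationResults", "embed_annotations",
           "permutation_pvalues", "fdr_adjust", "assign_annotations_to_axes",
           "assign_genes_to_axes", "capture_stats", "dimensionality_scan",
           "ScanResult"]


def embed_annotations(M, B: np.ndarray) -> np.ndarray:
    """Least-squares embedding of annotations: ``U = M @ pinv(B^T)``.

    ``M`` may be an :class:`AnnotationTable` or a t x n array; ``B`` must
    have full column rank (for an orthonormal basis this reduces to
    ``U = M @ B``).
    """
    Mm = M.M if isinstance(M, AnnotationTable) else np.asarray(M, float)
    B = np.asarray(B, dtype=float)
    if Mm.shape[1] != B.shape[0]:
        raise ValueError("gene axes of M and B do not align")
    if np.linalg.matrix_rank(B) < B.shape[1]:
        raise ValueError("basis B is rank-deficient")
    return Mm @ np.linalg.pinv(B.T)


def permutation_pvalues(M, B: np.ndarray, n_perm: int = 100_000,
                        seed: int = 0, tail: str = "one") -> np.ndarray:
    """Empirical p-values for every (annotation, axis) coordinate.

    Each permutation applies one uniform random permutation to the gene
    columns of ``M`` (destroying the gene-embedding correspondence while
    preserving all marginals) and re-embeds.  ``c`` counts permutations
    whose random coordinate is >= the observed one; the p-value is
    ``(c+1)/(n_perm+1)``, so it lies in [1/(n_perm+1), 1].

    ``tail='two'`` compares absolute values, for sign-unconstrained
    embedding spaces.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if tail not in ("one", "two"):
        raise ValueError("tail must be 'one' or 'two'")
    Mm = M.M if isinstance(M, AnnotationTable) else np.asarray(M, float)
    K = np.linalg.pinv(np.asarray(B, float).T)        # n x d
    U = Mm @ K
    obs = np.abs(U) if tail == "two" else U
    rng = np.random.default_rng(seed)
    n = Mm.shape[1]
    c = np.zeros_like(U, dtype=np.int64)
    for _ in range(n_perm):
        # column permutation of M == row permutation of pinv(B^T)
        R = Mm @ K[rng.permutation(n)]
        r = np.abs(R) if tail == "two" else R
        c += obs <= r
    return (c + 1) / (n_perm + 1)


def fdr_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg across axes, independently for each annotation row."""
    p = np.asarray(pvalues, dtype=float)
    return np.vstack([bh_adjust(row) for row in p])


def assign_annotations_to_axes(U: np.ndarray, qvalues: np.ndarray,
                               alpha: float = 0.05) -> dict[int, int]:
    """Hard-cluster annotations onto axes.

    Annotation ``i`` maps to axis ``j`` iff ``j`` is the argmax of row
    ``u_i`` (ties -> lowest axis index) and ``q[i, j] <= alpha``;
    otherwise it stays unassigned.
    """
    U = np.asarray(U, dtype=float)
    q = np.asarray(qvalues, dtype=float)
    if U.shape != q.shape:
        raise ValueError("U and qvalues must have the same shape")
    out: dict[int, int] = {}
    for i in range(U.shape[0]):
        j = int(np.argmax(U[i]))
        if q[i, j] <= alpha:
            out[i] = j
    return out


def assign_genes_to_axes(E: np.ndarray) -> dict[int, int]:
    """Assign each gene to the axis of its largest embedding coordinate.

    All-zero rows stay unassigned (reported by omission from the map).
    Ties break to the lowest axis index.
    """
    E = np.asarray(E, dtype=float)
    out: dict[int, int] = {}
    for i, row in enumerate(E):
        if np.all(row == 0):
            continue
        out[i] = int(np.argmax(row))
    return out


def capture_stats(term_to_axis: dict[int, int], d: int, t: int
                  ) -> dict[str, float]:
    """Axis-level capture summary.

    Returns the percentage of axes with at least one associated term
    (``pct_axes``), the percentage of terms associated with any axis
    (``pct_terms``), and the mean number of terms per annotated axis
    (0 when nothing is assigned).
    """
    axes_hit = set(term_to_axis.values())
    n_assigned = len(term_to_axis)
    return {
        "pct_axes": 100.0 * len(axes_hit) / d if d else 0.0,
        "pct_terms": 100.0 * n_assigned / t if t else 0.0,
        "terms_per_axis": (n_assigned / len(axes_hit)) if axes_hit else 0.0,
    }


class AxisAnnotator:
    """Model associating an annotation table with the axes of a basis.

    Parameters
    ----------
    table : AnnotationTable
        Columns aligned with the node order underlying ``B``.
    B : ndarray of shape (n, d)
        Basis of the gene embedding space (columns = axes).
    E : ndarray of shape (n, d), optional
        Gene embedding matrix; enables the gene -> axis map.
    """

    def __init__(self, table: AnnotationTable, B: np.ndarray,
                 E: np.ndarray | None = None):
        if table.n_genes != np.asarray(B).shape[0]:
            raise ValueError("annotation table and basis do not align")
        self.table = table
        self.B = np.asarray(B, dtype=float)
        self.E = None if E is None else np.asarray(E, dtype=float)

    @classmethod
    def from_decomposition(cls, table: AnnotationTable,
                           res: NMTFResults) -> "AxisAnnotator":
        return cls(table, res.B, res.E)

    def fit(self, n_perm: int = 100_000, seed: int = 0,
            alpha: float = 0.05, tail: str = "one"
            ) -> "AxisAnnotationResults":
        U = embed_annotations(self.table, self.B)
        p = permutation_pvalues(self.table, self.B, n_perm=n_perm,
                                seed=seed, tail=tail)
        q = fdr_adjust(p)
        term_to_axis = assign_annotations_to_axes(U, q, alpha=alpha)
        gene_to_axis = assign_genes_to_axes(self.E) \
            if self.E is not None else {}
        return AxisAnnotationResults(
            model=self, U=U, pvalues=p, qvalues=q,
            term_to_axis=term_to_axis, gene_to_axis=gene_to_axis,
            n_perm=n_perm, seed=seed, alpha=alpha, tail=tail)


@dataclass
class AxisAnnotationResults:
    """Fitted annotation -> axis association."""

    model: AxisAnnotator = field(repr=False)
    U: np.ndarray = field(repr=False)
    pvalues: np.ndarray = field(repr=False)
    qvalues: np.ndarray = field(repr=False)
    term_to_axis: dict[int, int]
    gene_to_axis: dict[int, int]
    n_perm: int
    seed: int
    alpha: float
    tail: str

    @property
    def d(self) -> int:
        return self.U.shape[1]

    @property
    def term_ids_by_axis(self) -> dict[int, list[str]]:
        """Axis -> list of associated term ids."""
        out: dict[int, list[str]] = {}
        terms = self.model.table.term_ids
        for i, j in sorted(self.term_to_axis.items()):
            out.setdefault(j, []).append(terms[i])
        return out

    @property
    def gene_ids_by_axis(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        genes = self.model.table.gene_ids
        for i, j in sorted(self.gene_to_axis.items()):
            out.setdefault(j, []).append(genes[i])
        return out

    def capture(self) -> dict[str, float]:
        return capture_stats(self.term_to_axis, self.d,
                             self.model.table.n_terms)

    def summary(self) -> str:
        cap = self.capture()
        lines = [
            "Axis annotation results",
            "=" * 41,
            f"terms x axes:       {self.U.shape[0]} x {self.d}",
            f"permutations:       {self.n_perm} (seed {self.seed},"
            f" {self.tail}-tailed)",
            f"FDR threshold:      {self.alpha}",
            f"terms associated:   {len(self.term_to_axis)}"
            f" ({cap['pct_terms']:.1f}%)",
            f"axes annotated:     {len(set(self.term_to_axis.values()))}"
            f" ({cap['pct_axes']:.1f}%)",
            f"terms per annotated axis: {cap['terms_per_axis']:.2f}",
        ]
        return "\n".join(lines)


@dataclass
class ScanResult:
    """Capture curve over a dimensionality grid and the selected d."""

    d_grid: list[int]
    pct_terms: list[float]
    pct_axes: list[float]
    selected_d: int
    results: dict[int, AxisAnnotationResults] = field(repr=False,
                                                      default_factory=dict)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.d_grid, self.pct_terms, marker="o",
                label="% terms captured")
        ax.plot(self.d_grid, self.pct_axes, marker="s",
                label="% axes annotated")
        ax.axvline(self.selected_d, ls="--", color="grey")
        ax.set_xlabel("dimensions")
        ax.set_ylabel("%")
        ax.legend()
        return ax


def select_plateau(d_grid, captured, tol: float = 2.0) -> int:
    """Smallest grid point whose capture is within ``tol`` (absolute
    percentage points) of the curve's maximum."""
    captured = list(captured)
    best = max(captured)
    for d, c in zip(d_grid, captured):
        if c >= best - tol:
            return d
    return d_grid[-1]


def dimensionality_scan(X, table: AnnotationTable, d_grid,
                        method: str = "onmtf", n_perm: int = 1000,
                        seed: int = 0, alpha: float = 0.05,
                        plateau_tol: float = 2.0, max_iter: int = 500,
                        keep_results: bool = False) -> ScanResult:
    """Run the full embed -> annotate pipeline over a grid of dimensions.

    Reports the %-terms-captured curve and selects the smallest
    dimensionality within ``plateau_tol`` percentage points of the
    maximum capture (the capture curve typically rises and then
    flattens once the axes resolve the network's functional modules).
    """
    d_grid = list(d_grid)
    if len(d_grid) < 2:
        raise ValueError("need a grid of at least two dimensionalities")
    if method not in ("onmtf", "nmtf"):
        raise ValueError("method must be 'onmtf' or 'nmtf'")
    pct_terms, pct_axes, results = [], [], {}
    for d in d_grid:
        res = NMTF(X, rank=d, orthonormal=(method == "onmtf")
                   ).fit(max_iter=max_iter)
        ann = AxisAnnotator.from_decomposition(table, res).fit(
            n_perm=n_perm, seed=seed, alpha=alpha)
        cap = ann.capture()
        pct_terms.append(cap["pct_terms"])
        pct_axes.append(cap["pct_axes"])
        if keep_results:
            results[d] = ann
    selected = select_plateau(d_grid, pct_terms, tol=plateau_tol)
    return ScanResult(d_grid=d_grid, pct_terms=pct_terms,
                      pct_axes=pct_axes, selected_d=selected,
                      results=results)
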