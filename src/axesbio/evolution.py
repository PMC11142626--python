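"""Evolutionary conservation of annotations and ASFAs.

The *conservation degree* of an annotation is the number of distinct
taxa (out of a 20-taxon catalog) in which it appears; the more taxa, the
more evolutionarily conserved the function.  Conservation relates to
functional specificity (it correlates positively with the number of
genes a term annotates and negatively with the term's depth in the
ontology) and to embedding geometry (highly conserved terms sit farther
from the rest of the terms in the embedding space).  Terms are
categorized as 'generic' (degree 1-4), 'specific' (degree 17-20) or
'background'.

An ASFA inherits the taxon union of the terms on its axis and is
classified by evolutionary origin with a three-rule cascade:
'prokaryotes' if any taxon is a prokaryote; 'eukaryotes' if all taxa
are non-vertebrate eukaryotes; 'vertebrates' if all taxa are eukaryotes
and at least one is a vertebrate.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy.spatial.distance import squareform, pdist

from ._stats import pearson, spearman
from .annotations import AnnotationTable
from .asfa import ASFA

__all__ = ["TaxonCatalog", "conservation_degree",
           "specificity_correlations", "distance_vs_conservation",
           "asfa_conservation", "classify_evolution", "categorize_degree"]

PROKARYOTE = "prokaryote"
EUKARYOTE = "eukaryote"
VERTEBRATE = "vertebrate"
_CLASSES = (PROKARYOTE, EUKARYOTE, VERTEBRATE)


@dataclass
class TaxonCatalog:
    """Map taxon id -> clade class for the annotation taxa."""

    clade: dict[int, str]
    names: dict[int, str]

    def __post_init__(self) -> None:
        bad = {t: c for t, c in self.clade.items() if c not in _CLASSES}
        if bad:
            raise ValueError(f"unknown clade classes: {bad}")

    @classmethod
    def default(cls) -> "TaxonCatalog":
        """The packaged 20-taxon gene2go catalog."""
        text = resources.files("axesbio.data").joinpath(
            "gene2go_taxa.tsv").read_text()
        clade, names = {}, {}
        for line in text.splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            tid, cl, name = line.split("\t")
            clade[int(tid)] = cl
            names[int(tid)] = name
        return cls(clade, names)

    @property
    def total_taxa(self) -> int:
        return len(self.clade)

    def __contains__(self, taxon: int) -> bool:
        return taxon in self.clade


def conservation_degree(term: str, table: AnnotationTable) -> int:
    """Number of distinct taxa in which an annotation appears."""
    if term not in table.term_taxa:
        raise KeyError(f"term {term!r} not in annotation table")
    taxa = table.term_taxa[term]
    if not taxa:
        raise ValueError(f"term {term!r} has an empty taxon set")
    return len(taxa)


def specificity_correlations(table: AnnotationTable, dag
                             ) -> tuple[float, float]:
    """Pearson correlations of conservation degree with two specificity
    measures: the per-term annotated-gene count (expected positive) and
    the term's ontology level (expected negative)."""
    terms = [t for t in table.term_ids if table.term_taxa.get(t)]
    if len(terms) < 3:
        raise ValueError("need at least 3 terms with taxon data")
    deg = [conservation_degree(t, table) for t in terms]
    counts = [table.M[table.term_ids.index(t)].sum() for t in terms]
    levels = [dag.level[t] for t in terms]
    r_genes, _ = pearson(deg, counts)
    r_level, _ = pearson(deg, levels)
    return r_genes, r_level


def categorize_degree(degree: int) -> str:
    """'generic' (1-4), 'specific' (17-20) or 'background'."""
    if 1 <= degree <= 4:
        return "generic"
    if 17 <= degree <= 20:
        return "specific"
    return "background"


def distance_vs_conservation(U: np.ndarray, table: AnnotationTable
                             ) -> dict:
    """Relate embedding-space isolation to conservation degree.

    For each term: the mean Euclidean distance of its embedding row to
    all other terms.  Reports the Spearman correlation of this distance
    with the conservation degree, the mean distance per degree, the
    degree at which the per-degree means jump most between consecutive
    observed degrees, and per-term category labels.
    """
    U = np.asarray(U, dtype=float)
    if U.shape[0] != table.n_terms:
        raise ValueError("U rows must align with the annotation table")
    if U.shape[0] < 2:
        raise ValueError("need at least 2 terms")
    degrees = np.array([conservation_degree(t, table)
                        for t in table.term_ids])
    D = squareform(pdist(U))
    mean_dist = D.sum(axis=1) / (U.shape[0] - 1)
    if np.all(mean_dist == mean_dist[0]) or np.all(degrees == degrees[0]):
        rho = float("nan")
    else:
        rho, _ = spearman(degrees, mean_dist)
    per_degree = {int(d): float(mean_dist[degrees == d].mean())
                  for d in np.unique(degrees)}
    jump_at = None
    ds = sorted(per_degree)
    if len(ds) > 1:
        diffs = [(per_degree[b] - per_degree[a], b)
                 for a, b in zip(ds, ds[1:])]
        jump_at = max(diffs)[1]
    categories = {t: categorize_degree(int(d))
                  for t, d in zip(table.term_ids, degrees)}
    return {"spearman": rho, "mean_distance_per_degree": per_degree,
            "jump_degree": jump_at, "categories": categories,
            "mean_distances": mean_dist}


def asfa_conservation(asfa: ASFA, table: AnnotationTable) -> set[int]:
    """Taxon union over the terms behind an ASFA (its conservation
    degree is the size of this union, which dominates every member's
    own degree).  Also stored on the ASFA."""
    if asfa.source != "go_terms":
        raise ValueError("conservation is defined for term-derived ASFAs")
    if not asfa.item_ids:
        raise ValueError(f"axis {asfa.axis_id} has no associated terms")
    union: set[int] = set()
    for term in asfa.item_ids:
        union |= table.term_taxa.get(term, set())
    if not union:
        raise ValueError(f"axis {asfa.axis_id} terms carry no taxon data")
    asfa.taxon_union = union
    return union


def classify_evolution(taxon_union: set[int],
                       catalog: TaxonCatalog | None = None) -> str:
    """Three-rule evolutionary-origin cascade over a taxon union.

    1. 'prokaryotes'  if at least one taxon is a prokaryote;
    2. 'eukaryotes'   if all taxa are eukaryotes and none is a vertebrate;
    3. 'vertebrates'  if all taxa are eukaryotes and at least one is a
       vertebrate.
    """
    if catalog is None:
        catalog = TaxonCatalog.default()
    if not taxon_union:
        raise ValueError("empty taxon union")
    unknown = [t for t in taxon_union if t not in catalog]
    if unknown:
        raise KeyError(f"taxa missing from the catalog: {unknown}")
    clades = {catalog.clade[t] for t in taxon_union}
    if PROKARYOTE in clades:
        return "prokaryotes"
    if VERTEBRATE not in clades:
        return "eukaryotes"
    return "vertebrates"
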