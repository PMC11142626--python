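"""Ontology DAG handling: parsing, annotation propagation, semantic similarity.

Functional annotations (e.g. Gene Ontology terms) live in a directed
acyclic graph linked by ``is_a`` and ``part_of`` relations.  Genes are
annotated not only with their directly recorded terms but with every
ancestor of those terms, so high-level processes are represented by the
union of their descendants' gene sets.  Terms annotating three or fewer
genes are excluded as uninformative.

Semantic similarity between two terms uses Lin's measure,

    sim(t1, t2) = 2 * IC(MICA) / (IC(t1) + IC(t2)),

where IC(t) = -log(n_genes(t) / n_genes(corpus)) is the information
content computed on the propagated annotation corpus and MICA is the
common ancestor with maximal IC.  The undirected shortest-path distance
in the DAG serves as an alternative relatedness measure.
"""

from __future__ import annotations

import math
import warnings
from collections import deque
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .annotations import AnnotationTable

__all__ = ["OntologyDAG", "parse_obo", "propagate_annotations",
           "filter_rare_terms", "information_content", "lin_similarity",
           "term_shortest_path"]

_KEPT_RELATIONS = ("is_a", "part_of")


@dataclass
class OntologyDAG:
    """Ontology restricted to is_a / part_of links.

    Attributes
    ----------
    parents : dict
        term -> set of (parent term, relation) pairs.
    roots : set
        Terms with no parents (one per namespace in a multi-root file).
    level : dict
        term -> minimal hop count from a root (roots are level 0).
    """

    parents: dict[str, set[tuple[str, str]]]
    names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        g = self.to_networkx()
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ValueError(f"ontology graph contains a cycle: {cycle}")
        self.roots = {t for t, ps in self.parents.items() if not ps}
        # min-hop level via BFS from all roots over child-ward edges
        children: dict[str, set[str]] = {t: set() for t in self.parents}
        for t, ps in self.parents.items():
            for p, _rel in ps:
                if p not in self.parents:
                    raise ValueError(f"parent term {p!r} missing from ontology")
                children[p].add(t)
        self.level: dict[str, int] = {r: 0 for r in self.roots}
        queue = deque(self.roots)
        while queue:
            t = queue.popleft()
            for c in children[t]:
                if c not in self.level:
                    self.level[c] = self.level[t] + 1
                    queue.append(c)

    @property
    def terms(self) -> set[str]:
        return set(self.parents)

    def __contains__(self, term: str) -> bool:
        return term in self.parents

    def ancestors(self, term: str, include_self: bool = True) -> set[str]:
        """All terms reachable by following is_a/part_of links upward."""
        if term not in self.parents:
            raise KeyError(term)
        seen = {term}
        queue = deque([term])
        while queue:
            t = queue.popleft()
            for p, _rel in self.parents[t]:
                if p not in seen:
                    seen.add(p)
                    queue.append(p)
        if not include_self:
            seen.discard(term)
        return seen

    def to_networkx(self) -> nx.DiGraph:
        """Child -> parent digraph with a ``relation`` edge attribute."""
        g = nx.DiGraph()
        g.add_nodes_from(self.parents)
        for t, ps in self.parents.items():
            for p, rel in ps:
                g.add_edge(t, p, relation=rel)
        return g


def parse_obo(path) -> OntologyDAG:
    """Parse an OBO 1.2-style file, keeping is_a and part_of links only.

    Obsolete terms are dropped; cycles raise.  Parsing is delegated to
    :mod:`obonet`.
    """
    import obonet

    g = obonet.read_obo(path, ignore_obsolete=True)
    parents: dict[str, set[tuple[str, str]]] = {t: set() for t in g.nodes}
    names = {t: data.get("name", "") for t, data in g.nodes(data=True)}
    # obonet edges run child -> parent keyed by the relation type
    for child, parent, rel in g.edges(keys=True):
        if rel in _KEPT_RELATIONS:
            parents[child].add((parent, rel))
    return OntologyDAG(parents, names)


def propagate_annotations(gene2term, dag: OntologyDAG,
                          gene_order=None) -> AnnotationTable:
    """Extend raw gene-term(-taxon) records to all ontology ancestors.

    Parameters
    ----------
    gene2term : iterable
        Records of ``(gene, term)`` or ``(gene, term, taxon)``.  Terms
        not resolvable in the DAG are dropped with a warning.  Taxon
        labels are unioned upward along with the terms.
    dag : OntologyDAG
    gene_order : list of str, optional
        Column ordering of the resulting incidence matrix; defaults to
        the sorted set of annotated genes.

    Returns
    -------
    AnnotationTable
        Binary term x gene incidence over the transitive closure, with
        per-term taxon sets and ontology levels.
    """
    records = list(gene2term)
    if not records:
        raise ValueError("empty annotation input")
    dropped = set()
    per_gene: dict[str, set[str]] = {}
    term_taxa: dict[str, set[int]] = {}
    closure_cache: dict[str, set[str]] = {}
    for rec in records:
        gene, term = str(rec[0]), str(rec[1])
        taxon = int(rec[2]) if len(rec) > 2 else None
        if term not in dag:
            dropped.add(term)
            continue
        if term not in closure_cache:
            closure_cache[term] = dag.ancestors(term)
        closure = closure_cache[term]
        per_gene.setdefault(gene, set()).update(closure)
        if taxon is not None:
            for t in closure:
                term_taxa.setdefault(t, set()).add(taxon)
    if dropped:
        warnings.warn(
            f"dropped {len(dropped)} term ids absent from the ontology",
            stacklevel=2)
    if not per_gene:
        raise ValueError("no annotations survived term resolution")
    genes = list(gene_order) if gene_order is not None \
        else sorted(per_gene)
    terms = sorted({t for ts in per_gene.values() for t in ts})
    gidx = {g: j for j, g in enumerate(genes)}
    M = np.zeros((len(terms), len(genes)))
    tidx = {t: i for i, t in enumerate(terms)}
    for gene, ts in per_gene.items():
        if gene not in gidx:
            continue
        for t in ts:
            M[tidx[t], gidx[gene]] = 1.0
    return AnnotationTable(
        term_ids=terms, gene_ids=genes, M=M,
        term_taxa={t: term_taxa.get(t, set()) for t in terms},
        term_level={t: dag.level.get(t) for t in terms})


def filter_rare_terms(table: AnnotationTable,
                      min_genes: int = 4) -> AnnotationTable:
    """Drop terms annotating fewer than ``min_genes`` genes (default: <=3)."""
    keep = [i for i, t in enumerate(table.term_ids)
            if table.M[i].sum() >= min_genes]
    if not keep:
        raise ValueError("no terms survive the rare-term filter")
    return table.subset_terms([table.term_ids[i] for i in keep])


def information_content(table: AnnotationTable, dag: OntologyDAG
                        ) -> dict[str, float]:
    """IC(t) = -log(n_genes(t) / n annotated genes), on the propagated table.

    Terms with zero annotated genes are excluded from the map.
    """
    counts = table.M.sum(axis=1)
    corpus = int((table.M.sum(axis=0) > 0).sum())
    if corpus == 0:
        raise ValueError("annotation table annotates no genes")
    ic = {}
    for term, c in zip(table.term_ids, counts):
        if c > 0:
            ic[term] = -math.log(c / corpus)
    return ic


def lin_similarity(t1: str, t2: str, dag: OntologyDAG,
                   ic: dict[str, float]) -> float:
    """Lin's semantic similarity in [0, 1].

    2*IC(MICA)/(IC(t1)+IC(t2)) with MICA the common ancestor of maximal
    information content; 0 when the terms share no informative ancestor
    (e.g. across namespaces of a multi-root ontology).
    """
    if t1 not in ic or t2 not in ic:
        raise KeyError("both terms must have an information content")
    if t1 == t2:
        return 1.0 if ic[t1] > 0 else 0.0
    common = dag.ancestors(t1) & dag.ancestors(t2)
    common = {t for t in common if t in ic}
    if not common:
        warnings.warn(f"no common ancestor for {t1} and {t2}", stacklevel=2)
        return 0.0
    mica_ic = max(ic[t] for t in common)
    denom = ic[t1] + ic[t2]
    if denom == 0:
        return 0.0
    return 2.0 * mica_ic / denom


def term_shortest_path(t1: str, t2: str, dag: OntologyDAG) -> float:
    """Undirected shortest-path length between two terms in the DAG.

    Disconnected pairs return ``math.inf``.
    """
    if t1 not in dag or t2 not in dag:
        raise KeyError("both terms must be in the ontology")
    g = dag.to_networkx().to_undirected()
    try:
        return float(nx.shortest_path_length(g, t1, t2))
    except nx.NetworkXNoPath:
        return math.inf
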