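"""Synthetic fixtures with planted structure.

Generates everything the pipeline consumes — a stochastic-block-model
(SBM) network with planted functional modules, a toy ontology DAG (one
root, one branch per module, leaves under each branch), module-aligned
gene annotations with taxon labels, term definition texts drawn from
module-specific vocabularies, and gene descriptions — so every stage is
testable end to end without any download.  The planted module labels
are returned as ground truth.

Default conditions: 300 genes in 8 modules with assortative edge
probabilities p_in=0.3 and p_out=0.01 (dense within-module wiring,
sparse background, the regime where the embedding axes should align
with the modules), 8 leaf terms per module each annotating half of its
module's genes, and 20 taxa whose assignment makes alternating branches
'ancient' (broad taxon span including the prokaryote) or 'recent'
(small vertebrate-only span).

All randomness flows from the single spec seed through spawned
generators, so each sub-fixture is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .annotations import AnnotationTable
from .evolution import TaxonCatalog
from .network import Network
from .ontology import OntologyDAG, filter_rare_terms, propagate_annotations

__all__ = ["SyntheticSpec", "make_network", "make_ontology_and_annotations",
           "make_gene_descriptions", "write_fixture_dir"]

_STOPWORD_PAD = "the of and in to a is for with that"


@dataclass
class SyntheticSpec:
    """Conditions of a synthetic study."""

    n_genes: int = 300
    k_modules: int = 8
    p_in: float = 0.3
    p_out: float = 0.01
    n_terms_per_module: int = 8
    term_gene_coverage: float = 0.5
    n_taxa: int = 20
    words_per_module: int = 12
    words_per_text: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.p_in > self.p_out:
            raise ValueError("planting must be assortative: p_in > p_out")
        if self.n_genes < 2 * self.k_modules:
            raise ValueError("modules need at least 2 genes each")

    def rngs(self, n: int) -> list[np.random.Generator]:
        """Independent child generators spawned from the spec seed."""
        ss = np.random.SeedSequence(self.seed)
        return [np.random.default_rng(s) for s in ss.spawn(n)]

    def gene_ids(self) -> list[str]:
        width = len(str(self.n_genes - 1))
        return [f"g{i:0{width}d}" for i in range(self.n_genes)]

    def module_sizes(self) -> list[int]:
        base, extra = divmod(self.n_genes, self.k_modules)
        return [base + (1 if m < extra else 0)
                for m in range(self.k_modules)]


def make_network(spec: SyntheticSpec) -> tuple[Network, dict[str, int]]:
    """Seeded SBM draw; returns the network and gene -> module labels.

    Regenerates up to 100 times until the draw is connected, then
    errors (an impossible regime such as p_out=0 with several modules
    never connects).
    """
    sizes = spec.module_sizes()
    probs = [[spec.p_in if a == b else spec.p_out
              for b in range(spec.k_modules)] for a in range(spec.k_modules)]
    (rng,) = spec.rngs(1)
    genes = spec.gene_ids()
    labels = {}
    start = 0
    for m, size in enumerate(sizes):
        for g in genes[start:start + size]:
            labels[g] = m
        start += size
    for _ in range(100):
        g = nx.stochastic_block_model(
            sizes, probs, seed=int(rng.integers(2**31 - 1)))
        if nx.is_connected(g):
            A = nx.to_numpy_array(g, nodelist=range(spec.n_genes))
            return Network(genes, A), labels
    raise ValueError("no connected SBM draw in 100 retries; "
                     "increase p_in/p_out or module sizes")


def _module_vocab(spec: SyntheticSpec, module: int) -> list[str]:
    return [f"kw{module:02d}x{i:02d}" for i in range(spec.words_per_module)]


def _module_taxa(spec: SyntheticSpec, module: int,
                 catalog: TaxonCatalog) -> list[int]:
    """Taxon pool per module: even branches are evolutionarily ancient
    (span most of the catalog including the prokaryote), odd branches
    are recent (vertebrates only)."""
    taxa = sorted(catalog.clade)[: spec.n_taxa]
    verts = [t for t in taxa if catalog.clade[t] == "vertebrate"]
    if module % 2 == 0:
        return taxa
    return verts[: max(2, len(verts) // 2)]


def make_ontology_and_annotations(
        spec: SyntheticSpec, labels: dict[str, int],
        catalog: TaxonCatalog | None = None,
) -> tuple[OntologyDAG, AnnotationTable, dict[str, str], dict[str, int]]:
    """Toy ontology plus module-aligned, taxon-labelled annotations.

    One root, one mid-level branch per module, ``n_terms_per_module``
    leaves per branch.  Each leaf annotates a seeded random
    ``term_gene_coverage`` fraction of its module's genes (erroring if
    that is fewer than 4 genes, which would not survive the rare-term
    filter); its taxon set is a seeded random subset of its branch's
    taxon pool.  Leaf definition texts mix module-specific vocabulary
    with common stop words.

    Returns the DAG, the propagated and rare-term-filtered annotation
    table (columns in gene-id order), the term texts, and the planted
    leaf-term -> module map.
    """
    if catalog is None:
        catalog = TaxonCatalog.default()
    _, rng_genes, rng_taxa, rng_text = spec.rngs(4)
    by_module: dict[int, list[str]] = {}
    for g, m in sorted(labels.items()):
        by_module.setdefault(m, []).append(g)

    parents: dict[str, set[tuple[str, str]]] = {"T:root": set()}
    names = {"T:root": "cellular process root"}
    texts: dict[str, str] = {"T:root": "generic " + _STOPWORD_PAD}
    records: list[tuple[str, str, int]] = []
    term_module: dict[str, int] = {}
    for m in range(spec.k_modules):
        mid = f"T:mid{m:02d}"
        rel = "is_a" if m % 2 == 0 else "part_of"
        parents[mid] = {("T:root", rel)}
        names[mid] = f"module {m} branch"
        vocab = _module_vocab(spec, m)
        texts[mid] = " ".join(vocab[:3]) + " " + _STOPWORD_PAD
        pool = _module_taxa(spec, m, catalog)
        module_genes = by_module[m]
        n_cover = int(round(spec.term_gene_coverage * len(module_genes)))
        if n_cover < 4:
            raise ValueError(
                "term_gene_coverage covers fewer than 4 genes; "
                "use larger modules or higher coverage")
        for i in range(spec.n_terms_per_module):
            leaf = f"T:m{m:02d}l{i:02d}"
            parents[leaf] = {(mid, "is_a")}
            names[leaf] = f"module {m} leaf {i}"
            term_module[leaf] = m
            words = rng_text.choice(vocab, size=spec.words_per_text,
                                    replace=True)
            texts[leaf] = " ".join(words) + " " + _STOPWORD_PAD
            chosen = rng_genes.choice(module_genes, size=n_cover,
                                      replace=False)
            n_tax = int(rng_taxa.integers(1, len(pool) + 1))
            leaf_taxa = rng_taxa.choice(pool, size=n_tax, replace=False)
            for gene in chosen:
                for taxon in leaf_taxa:
                    records.append((gene, leaf, int(taxon)))
    dag = OntologyDAG(parents, names)
    table = propagate_annotations(records, dag,
                                  gene_order=sorted(labels))
    table = filter_rare_terms(table, min_genes=4)
    table = table.with_text(texts)
    return dag, table, texts, term_module


def make_gene_descriptions(spec: SyntheticSpec,
                           labels: dict[str, int]) -> dict[str, str]:
    """Free-text gene descriptions drawn from each gene's module vocabulary."""
    *_, rng = spec.rngs(5)
    out = {}
    for g, m in sorted(labels.items()):
        vocab = _module_vocab(spec, m)
        words = rng.choice(vocab, size=spec.words_per_text, replace=True)
        out[g] = " ".join(words) + " " + _STOPWORD_PAD
    return out


def _write_obo(dag: OntologyDAG, path) -> None:
    lines = ["format-version: 1.2", ""]
    for term in sorted(dag.parents):
        lines += [f"[Term]", f"id: {term}",
                  f"name: {dag.names.get(term, term)}"]
        for parent, rel in sorted(dag.parents[term]):
            if rel == "is_a":
                lines.append(f"is_a: {parent} ! {dag.names.get(parent, '')}")
            else:
                lines.append(
                    f"relationship: part_of {parent} "
                    f"! {dag.names.get(parent, '')}")
        lines.append("")
    with open(path, "w") as fh:
        fh.write("\n".join(lines))


def write_fixture_dir(spec: SyntheticSpec, out_dir) -> dict[str, str]:
    """Write a complete fixture in the dialects the readers consume.

    Produces ``edges.tsv`` (two-column edge list), ``ontology.obo``,
    ``gene2go.tsv`` (gene, term, taxon), ``term_text.tsv``,
    ``gene_desc.tsv`` and ``modules.tsv`` (planted labels).
    """
    import pathlib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    network, labels = make_network(spec)
    dag, table, texts, term_module = make_ontology_and_annotations(
        spec, labels)
    descs = make_gene_descriptions(spec, labels)

    from .network import save_edgelist

    save_edgelist(network, out / "edges.tsv")
    _write_obo(dag, out / "ontology.obo")
    with open(out / "gene2go.tsv", "w") as fh:
        fh.write("# gene\tterm\ttaxon\n")
        for i, term in enumerate(table.term_ids):
            for j, gene in enumerate(table.gene_ids):
                if table.M[i, j]:
                    for taxon in sorted(table.term_taxa.get(term, ())):
                        fh.write(f"{gene}\t{term}\t{taxon}\n")
    with open(out / "term_text.tsv", "w") as fh:
        for term, text in sorted(texts.items()):
            fh.write(f"{term}\t{text}\n")
    with open(out / "gene_desc.tsv", "w") as fh:
        for gene, text in sorted(descs.items()):
            fh.write(f"{gene}\t{text}\n")
    with open(out / "modules.tsv", "w") as fh:
        for gene, m in sorted(labels.items()):
            fh.write(f"{gene}\t{m}\n")
    return {name: str(out / name) for name in
            ("edges.tsv", "ontology.obo", "gene2go.tsv",
             "term_text.tsv", "gene_desc.tsv", "modules.tsv")}
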