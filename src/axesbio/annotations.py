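"""Gene-annotation tables: binary term x gene incidence plus term metadata."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["AnnotationTable", "load_gene2go", "load_text_table"]


@dataclass
class AnnotationTable:
    """Binary incidence between annotation terms and genes.

    ``M[i, j] == 1`` iff term ``term_ids[i]`` annotates gene
    ``gene_ids[j]``.  Optional per-term metadata carries the free-text
    definition, the set of taxa in which the term appears and the term's
    depth in the ontology.
    """

    term_ids: list[str]
    gene_ids: list[str]
    M: np.ndarray
    term_text: dict[str, str] = field(default_factory=dict)
    term_taxa: dict[str, set[int]] = field(default_factory=dict)
    term_level: dict[str, int | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=float)
        if self.M.shape != (len(self.term_ids), len(self.gene_ids)):
            raise ValueError("M shape does not match term/gene lists")
        if not np.all(np.isin(self.M, (0.0, 1.0))):
            raise ValueError("M must be binary")

    @property
    def n_terms(self) -> int:
        return len(self.term_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def genes_of(self, term: str) -> list[str]:
        i = self.term_ids.index(term)
        return [g for g, v in zip(self.gene_ids, self.M[i]) if v]

    def gene_counts(self) -> np.ndarray:
        """Number of genes annotated by each term (row sums)."""
        return self.M.sum(axis=1)

    def subset_terms(self, terms: list[str]) -> "AnnotationTable":
        idx = [self.term_ids.index(t) for t in terms]
        return AnnotationTable(
            term_ids=list(terms), gene_ids=list(self.gene_ids),
            M=self.M[idx].copy(),
            term_text={t: self.term_text[t] for t in terms
                       if t in self.term_text},
            term_taxa={t: set(self.term_taxa.get(t, set())) for t in terms},
            term_level={t: self.term_level.get(t) for t in terms})

    def aligned_to(self, node_ids: list[str]) -> "AnnotationTable":
        """Reindex columns to a network's node order.

        Genes absent from the table get all-zero columns; genes absent
        from the network are dropped.
        """
        gidx = {g: j for j, g in enumerate(self.gene_ids)}
        M = np.zeros((self.n_terms, len(node_ids)))
        for j, g in enumerate(node_ids):
            if g in gidx:
                M[:, j] = self.M[:, gidx[g]]
        return AnnotationTable(
            term_ids=list(self.term_ids), gene_ids=list(node_ids), M=M,
            term_text=dict(self.term_text),
            term_taxa={t: set(s) for t, s in self.term_taxa.items()},
            term_level=dict(self.term_level))

    def with_text(self, texts: dict[str, str]) -> "AnnotationTable":
        merged = dict(self.term_text)
        merged.update(texts)
        return AnnotationTable(
            term_ids=list(self.term_ids), gene_ids=list(self.gene_ids),
            M=self.M.copy(), term_text=merged,
            term_taxa={t: set(s) for t, s in self.term_taxa.items()},
            term_level=dict(self.term_level))


def load_gene2go(path) -> list[tuple[str, str, int]]:
    """Read a gene2go-style TSV: gene id, term id, taxon id per line.

    Lines starting with ``#`` are ignored.
    """
    records = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}: malformed line {lineno}")
            records.append((parts[0], parts[1], int(parts[2])))
    if not records:
        raise ValueError(f"{path}: no annotation records")
    return records


def load_text_table(path) -> dict[str, str]:
    """Read an id -> free text TSV (term definitions or gene descriptions)."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            ident, _, text = line.partition("\t")
            out[ident] = text
    return out
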