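"""Axes-Specific Functional Annotations (ASFAs).

Each annotated axis is summarized into a data-driven higher-level
annotation: the *document* of an axis is the concatenated free text of
the items associated with it (the definitions of its terms, or the
descriptions of its genes), the *corpus* is the collection of all axis
documents, and the ASFA is the set of words whose adapted TF-IDF score
in the axis document is strictly positive:

    TF-IDF(t, d) = (1 + log TF(t, d)) * log(N / DF(t))

with raw occurrence counts TF, document frequency DF and corpus size N
(natural logarithms; the base rescales scores without changing which
words score above zero).  English stop words are removed before
counting; remaining tokens are lowercased alphanumeric runs of length
at least two.  A word present in every document scores zero everywhere
and never enters an ASFA; with a single document every IDF is zero and
all ASFAs are empty.
"""

from __future__ import annotations

import math
import re
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources

__all__ = ["Corpus", "ASFA", "load_stopwords", "tokenize", "tfidf",
           "build_asfas"]

_TOKEN_RE = re.compile(r"[a-z0-9]{2,}")


def load_stopwords() -> frozenset[str]:
    """English stop-word list shipped with the package."""
    text = resources.files("axesbio.data").joinpath(
        "stopwords_en.txt").read_text()
    return frozenset(w for w in text.split() if w)


def tokenize(text: str, stopwords: frozenset[str] | None = None) -> Counter:
    """Lowercased alphanumeric tokens (length >= 2) minus stop words.

    Returns a multiset (Counter) of token occurrences.
    """
    if stopwords is None:
        stopwords = load_stopwords()
    tokens = _TOKEN_RE.findall(text.lower())
    return Counter(t for t in tokens if t not in stopwords)


@dataclass
class Corpus:
    """Per-axis documents as token multisets."""

    documents: dict[int, Counter]

    @classmethod
    def from_texts(cls, texts_by_axis: dict[int, str],
                   stopwords: frozenset[str] | None = None) -> "Corpus":
        if stopwords is None:
            stopwords = load_stopwords()
        return cls({axis: tokenize(text, stopwords)
                    for axis, text in texts_by_axis.items()})

    @property
    def N(self) -> int:
        return len(self.documents)

    @property
    def vocabulary(self) -> set[str]:
        return {w for doc in self.documents.values() for w in doc}

    def document_frequency(self) -> Counter:
        df: Counter = Counter()
        for doc in self.documents.values():
            df.update(set(doc))
        return df


def tfidf(corpus: Corpus, log_base: float = math.e
          ) -> dict[int, dict[str, float]]:
    """Adapted TF-IDF score of every word in every document it occurs in.

    score(t, d) = (1 + log TF(t, d)) * log(N / DF(t)); words absent from
    a document receive no score there.
    """
    if corpus.N < 1:
        raise ValueError("corpus must contain at least one document")
    lb = math.log(log_base)
    df = corpus.document_frequency()
    n = corpus.N
    scores: dict[int, dict[str, float]] = {}
    for axis, doc in corpus.documents.items():
        scores[axis] = {
            w: (1 + math.log(tf) / lb) * (math.log(n / df[w]) / lb)
            for w, tf in doc.items()}
    return scores


@dataclass
class ASFA:
    """Axis-Specific Functional Annotation: TF-IDF-positive keywords.

    ``item_ids`` records the terms (or genes) whose texts form the axis
    document, so downstream conservation analysis can take taxon unions
    over them.
    """

    axis_id: int
    keywords: dict[str, float]
    source: str                      # 'go_terms' | 'gene_descriptions'
    item_ids: list[str] = field(default_factory=list)
    taxon_union: set[int] = field(default_factory=set)
    evolution_class: str = "unset"

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.keywords.values()):
            raise ValueError("ASFA keywords must have strictly positive scores")

    @property
    def n_items(self) -> int:
        return len(self.item_ids)

    def top_keywords(self, n: int = 10) -> list[str]:
        return [w for w, _ in sorted(self.keywords.items(),
                                     key=lambda kv: (-kv[1], kv[0]))[:n]]


def build_asfas(assoc, texts: dict[str, str],
                source: str = "go_terms",
                stopwords: frozenset[str] | None = None) -> list[ASFA]:
    """Summarize every annotated axis into an ASFA.

    Parameters
    ----------
    assoc : AxisAnnotationResults
        Supplies the term -> axis map (``source='go_terms'``) or the
        gene -> axis map (``source='gene_descriptions'``).
    texts : dict
        Term id -> definition text, or gene id -> description text.
    source : str
        Which association map drives the axis documents.

    Returns
    -------
    list of ASFA, one per annotated axis, sorted by axis index.  With a
    single annotated axis all IDFs are zero and the ASFA keyword sets
    are empty (valid, flagged by their emptiness).
    """
    if source == "go_terms":
        by_axis = assoc.term_ids_by_axis
    elif source == "gene_descriptions":
        by_axis = assoc.gene_ids_by_axis
    else:
        raise ValueError("source must be 'go_terms' or 'gene_descriptions'")
    if not by_axis:
        raise ValueError("no annotated axes to summarize")
    docs = {axis: " ".join(texts.get(i, "") for i in ids)
            for axis, ids in by_axis.items()}
    corpus = Corpus.from_texts(docs, stopwords=stopwords)
    scores = tfidf(corpus)
    out = []
    for axis in sorted(by_axis):
        kw = {w: s for w, s in scores[axis].items() if s > 0}
        out.append(ASFA(axis_id=axis, keywords=kw, source=source,
                        item_ids=list(by_axis[axis])))
    return out
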