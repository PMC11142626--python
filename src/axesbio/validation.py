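"""Coherence statistics and baselines for axis annotations.

Checks that the functional information captured by the axes is
biologically coherent: terms sharing an axis should be semantically
similar (intra- vs inter-axis semantic similarity, 'SeSi'), genes behind
same-axis functions should be close and densely connected in the source
network, and the axis geometry should agree with the pairwise
function-association view (cosine distances between annotation
embeddings).  A gene-centric baseline (spherical k-means clustering of
gene embeddings followed by hypergeometric enrichment) provides the
standard of comparison.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from ._stats import bh_adjust, hypergeom_tail, mann_whitney_u
from .annotations import AnnotationTable
from .network import Network

__all__ = ["intra_inter_sesi", "low_intra_axes", "gene_centric_baseline",
           "ppi_module_coherence", "fmm_agreement"]


def _pairs_by_axis(term_to_axis: dict[int, int]):
    """Split all pairs of assigned items into same-axis and cross-axis."""
    items = sorted(term_to_axis)
    same, cross = [], []
    for a, b in itertools.combinations(items, 2):
        (same if term_to_axis[a] == term_to_axis[b] else cross).append((a, b))
    return same, cross


def intra_inter_sesi(term_to_axis: dict[int, int], sim,
                     n_random: int = 1000, seed: int = 0) -> dict:
    """Mean same-axis vs cross-axis pairwise similarity.

    Parameters
    ----------
    term_to_axis : dict
        Item index -> axis index (only assigned items).
    sim : callable
        ``sim(i, j) -> float`` pairwise similarity between item indices.
    n_random : int
        Number of axis-size-preserving shuffles of the item -> axis map
        used for the random expectation.

    Returns
    -------
    dict with ``intra``, ``inter`` (NaN if no cross-axis pair),
    ``random_mean``, ``fold_vs_random`` (intra / random mean) and the
    one-tailed Mann-Whitney p-value of same-axis similarities exceeding
    cross-axis ones.
    """
    same, cross = _pairs_by_axis(term_to_axis)
    if not same:
        raise ValueError("no same-axis pair; nothing to evaluate")
    intra_vals = [sim(a, b) for a, b in same]
    inter_vals = [sim(a, b) for a, b in cross]
    intra = float(np.mean(intra_vals))
    inter = float(np.mean(inter_vals)) if inter_vals else math.nan
    rng = np.random.default_rng(seed)
    items = sorted(term_to_axis)
    axes = [term_to_axis[i] for i in items]
    rand_means = []
    for _ in range(n_random):
        shuffled = dict(zip(items, rng.permutation(axes)))
        s, _ = _pairs_by_axis(shuffled)
        rand_means.append(np.mean([sim(a, b) for a, b in s]))
    random_mean = float(np.mean(rand_means))
    if inter_vals:
        _, p = mann_whitney_u(intra_vals, inter_vals, alternative="greater")
    else:
        p = math.nan
    return {"intra": intra, "inter": inter, "random_mean": random_mean,
            "fold_vs_random": intra / random_mean if random_mean else math.inf,
            "mwu_p": p}


def low_intra_axes(term_to_axis: dict[int, int], sim,
                   n_random: int = 1000, alpha: float = 0.05,
                   seed: int = 0) -> list[int]:
    """Axes whose intra-axis mean similarity is significantly low.

    For each axis with >= 2 items, the null is the mean similarity of
    ``n_random`` equal-size random item sets drawn from the pool of all
    assigned items; the axis is flagged when its observed intra-axis
    mean falls below the ``alpha`` quantile of that null.  These are the
    axes grouping seemingly unrelated functions — candidates for new
    data-driven functional interactions.
    """
    rng = np.random.default_rng(seed)
    pool = sorted(term_to_axis)
    by_axis: dict[int, list[int]] = {}
    for i, j in term_to_axis.items():
        by_axis.setdefault(j, []).append(i)
    flagged = []
    for axis, members in sorted(by_axis.items()):
        k = len(members)
        if k < 2:
            continue
        obs = np.mean([sim(a, b)
                       for a, b in itertools.combinations(sorted(members), 2)])
        null = []
        for _ in range(n_random):
            draw = rng.choice(pool, size=k, replace=False)
            null.append(np.mean([sim(a, b) for a, b
                                 in itertools.combinations(sorted(draw), 2)]))
        if obs < np.quantile(null, alpha):
            flagged.append(axis)
    return flagged


def gene_centric_baseline(E: np.ndarray, table: AnnotationTable,
                          k: int | None = None, alpha: float = 0.05,
                          seed: int = 0) -> dict:
    """Classic gene-centric pipeline: cluster genes, enrich clusters.

    Genes are clustered by k-means on length-normalized embedding rows
    (cosine geometry, 10 seeded restarts, k defaults to the embedding
    dimensionality), and each (cluster, term) pair is tested for
    over-representation with the hypergeometric tail, BH-controlled at
    ``alpha`` across all pairs.

    Returns counts of clusters with at least one enriched term and of
    distinct enriched terms, plus the label array.
    """
    from sklearn.cluster import KMeans

    E = np.asarray(E, dtype=float)
    if k is None:
        k = E.shape[1]
    if k < 2:
        raise ValueError("k must be >= 2")
    norms = np.linalg.norm(E, axis=1, keepdims=True)
    Z = np.divide(E, norms, out=np.zeros_like(E), where=norms > 0)
    labels = KMeans(n_clusters=k, n_init=10, random_state=seed
                    ).fit_predict(Z)
    if len(set(labels)) < k:       # re-seed once on an empty cluster
        labels = KMeans(n_clusters=k, n_init=10, random_state=seed + 1
                        ).fit_predict(Z)
    n = table.n_genes
    pvals, keys = [], []
    for c in range(k):
        members = labels == c
        draws = int(members.sum())
        if draws == 0:
            continue
        for i in range(table.n_terms):
            succ = int(table.M[i].sum())
            overlap = int(table.M[i][members].sum())
            pvals.append(hypergeom_tail(overlap, n, succ, draws))
            keys.append((c, i))
    q = bh_adjust(np.asarray(pvals))
    enriched = [key for key, qq in zip(keys, q) if qq <= alpha]
    return {
        "labels": labels,
        "enriched_clusters": len({c for c, _ in enriched}),
        "enriched_terms": len({i for _, i in enriched}),
        "enriched_pairs": enriched,
    }


def ppi_module_coherence(network: Network, term_to_axis: dict[int, int],
                         table: AnnotationTable, n_random: int = 100,
                         seed: int = 0) -> dict:
    """Do same-axis functions map to cohesive regions of the network?

    Compares (a) mean pairwise shortest-path distance in the network
    between genes of same-axis term pairs vs cross-axis term pairs
    (one-tailed Mann-Whitney, same-axis smaller) and (b) the mean
    clustering coefficient of each axis's gene set vs size-matched
    random gene sets (seeded draws).  Axis gene sets smaller than 2 are
    skipped and reported.
    """
    import networkx as nx

    g = network.to_networkx()
    spl = dict(nx.all_pairs_shortest_path_length(g))

    def gene_set(term_idx: int) -> set[str]:
        return set(table.genes_of(table.term_ids[term_idx]))

    def mean_cross_distance(genes_a: set[str], genes_b: set[str]) -> float:
        dists = [spl[u][v] for u in genes_a for v in genes_b
                 if v in spl.get(u, {})]
        return float(np.mean(dists)) if dists else math.inf

    same, cross = _pairs_by_axis(term_to_axis)
    same_d = [mean_cross_distance(gene_set(a), gene_set(b)) for a, b in same]
    cross_d = [mean_cross_distance(gene_set(a), gene_set(b))
               for a, b in cross]
    same_f = [x for x in same_d if math.isfinite(x)]
    cross_f = [x for x in cross_d if math.isfinite(x)]
    if same_f and cross_f:
        _, dist_p = mann_whitney_u(cross_f, same_f, alternative="greater")
    else:
        dist_p = math.nan

    rng = np.random.default_rng(seed)
    by_axis: dict[int, set[str]] = {}
    for i, j in term_to_axis.items():
        by_axis.setdefault(j, set()).update(gene_set(i))
    cc_obs, cc_rand, skipped = [], [], []
    nodes = list(network.node_ids)
    for axis, genes in sorted(by_axis.items()):
        if len(genes) < 2:
            skipped.append(axis)
            continue
        cc_obs.append(np.mean([nx.clustering(g, x) for x in genes]))
        for _ in range(n_random):
            draw = rng.choice(nodes, size=len(genes), replace=False)
            cc_rand.append(np.mean([nx.clustering(g, x) for x in draw]))
    if cc_obs and cc_rand:
        _, cc_p = mann_whitney_u(cc_obs, cc_rand, alternative="greater")
    else:
        cc_p = math.nan
    return {
        "same_axis_mean_distance": float(np.mean(same_f)) if same_f
        else math.inf,
        "cross_axis_mean_distance": float(np.mean(cross_f)) if cross_f
        else math.inf,
        "distance_mwu_p": dist_p,
        "mean_clustering_obs": float(np.mean(cc_obs)) if cc_obs
        else math.nan,
        "mean_clustering_random": float(np.mean(cc_rand)) if cc_rand
        else math.nan,
        "clustering_mwu_p": cc_p,
        "skipped_axes": skipped,
    }


def fmm_agreement(U: np.ndarray, term_to_axis: dict[int, int]) -> float:
    """Agreement with the pairwise function-association view.

    Cosine distances between annotation-embedding rows: same-axis pairs
    should lie closer than cross-axis pairs (one-tailed Mann-Whitney,
    returns the p-value).
    """
    U = np.asarray(U, dtype=float)
    same, cross = _pairs_by_axis(term_to_axis)
    if not same or not cross:
        raise ValueError("need at least one pair in each group")

    def cos_dist(a: int, b: int) -> float:
        na, nb = np.linalg.norm(U[a]), np.linalg.norm(U[b])
        if na == 0 or nb == 0:
            return 1.0
        return 1.0 - float(U[a] @ U[b] / (na * nb))

    same_d = [cos_dist(a, b) for a, b in same]
    cross_d = [cos_dist(a, b) for a, b in cross]
    _, p = mann_whitney_u(cross_d, same_d, alternative="greater")
    return p
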