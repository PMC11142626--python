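"""Molecular networks and their random-walk PPMI representation.

A network is an undirected, unweighted graph whose nodes are gene
identifiers (in a protein-protein interaction network, nodes are
protein-coding genes and edges are physical bindings of their protein
products).  The network is represented for embedding purposes by its
positive pointwise mutual information (PPMI) matrix, a random-walk
co-occurrence statistic computed in closed form:

    PPMI = max{0, log( vol(N) * (1/T) * sum_{r=1..T} (D^-1 A)^r )}

where ``A`` is the adjacency matrix, ``D`` the diagonal degree matrix,
``vol(N)`` the sum of all entries of ``A`` and ``T`` the walk length
(default 10).  The PPMI matrix is a denser, higher-order-proximity-aware
representation than the adjacency matrix and is the input to the
tri-factorization models in :mod:`axesbio.nmtf`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["Network", "PPMIMatrix", "load_edgelist", "save_edgelist",
           "compute_ppmi", "drop_edges", "largest_connected_component"]

#: base of the logarithm in the PPMI formula; natural log is the PPMI
#: convention.  Switchable in one place for comparison with base-2 codes.
LOG_BASE: float = math.e


@dataclass
class Network:
    """Undirected, unweighted molecular network.

    Parameters
    ----------
    node_ids : list of str
        Gene identifiers, in the fixed (lexicographic) node order used by
        every matrix aligned with this network.
    adjacency : ndarray of shape (n, n)
        Symmetric 0/1 matrix with zero diagonal.
    """

    node_ids: list[str]
    adjacency: np.ndarray

    def __post_init__(self) -> None:
        A = np.asarray(self.adjacency, dtype=float)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("adjacency must be square")
        if len(self.node_ids) != A.shape[0]:
            raise ValueError("node_ids length does not match adjacency")
        if len(set(self.node_ids)) != len(self.node_ids):
            raise ValueError("node_ids must be unique")
        if A.shape[0] < 2:
            raise ValueError("a network needs at least 2 nodes")
        if not np.array_equal(A, A.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(A) != 0):
            raise ValueError("self-loops are not allowed (nonzero diagonal)")
        if not np.all(np.isin(A, (0.0, 1.0))):
            warnings.warn("weighted adjacency collapsed to 0/1", stacklevel=2)
            A = (A > 0).astype(float)
        self.adjacency = A

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    @property
    def volume(self) -> float:
        """vol(N): the sum of all adjacency entries (twice the edge count)."""
        return float(self.adjacency.sum())

    @property
    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)

    def edge_list(self) -> list[tuple[str, str]]:
        """Edges as sorted (u, v) pairs with u < v, in deterministic order."""
        iu, iv = np.nonzero(np.triu(self.adjacency))
        return [(self.node_ids[i], self.node_ids[j]) for i, j in zip(iu, iv)]

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.node_ids)
        g.add_edges_from(self.edge_list())
        return g

    @classmethod
    def from_edges(cls, edges) -> "Network":
        """Build a network from an iterable of (u, v) pairs.

        Self-loops are dropped and duplicate / reversed pairs are merged.
        Node order is lexicographic.
        """
        clean = {tuple(sorted((str(u), str(v)))) for u, v in edges
                 if str(u) != str(v)}
        if not clean:
            raise ValueError("no edges remain after dropping self-loops")
        nodes = sorted({x for e in clean for x in e})
        index = {g: i for i, g in enumerate(nodes)}
        A = np.zeros((len(nodes), len(nodes)))
        for u, v in clean:
            A[index[u], index[v]] = A[index[v], index[u]] = 1.0
        return cls(nodes, A)


@dataclass
class PPMIMatrix:
    """PPMI representation of a network; node order matches the source."""

    matrix: np.ndarray
    walk_length: int
    source_network: Network = field(repr=False)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if np.any(self.matrix < 0):
            raise ValueError("PPMI entries must be non-negative")

    @property
    def node_ids(self) -> list[str]:
        return self.source_network.node_ids

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    def save(self, directory) -> None:
        """Persist as dense .npy plus a node-order sidecar TSV."""
        import pathlib

        out = pathlib.Path(directory)
        out.mkdir(parents=True, exist_ok=True)
        np.save(out / "ppmi.npy", self.matrix)
        (out / "nodes.tsv").write_text(
            "".join(f"{g}\n" for g in self.node_ids))


def load_edgelist(path, self_loop_policy: str = "drop") -> Network:
    """Read a two-column whitespace/tab edge list into a :class:`Network`.

    Lines starting with ``#`` are ignored.  Self-loops are dropped and
    symmetric duplicates merged; node ordering is lexicographic.
    """
    if self_loop_policy != "drop":
        raise ValueError("only self_loop_policy='drop' is supported")
    edges = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(
                    f"{path}: malformed line {lineno}: {raw!r}")
            edges.append((parts[0], parts[1]))
    if not edges:
        raise ValueError(f"{path}: no edges found")
    return Network.from_edges(edges)


def save_edgelist(network: Network, path) -> None:
    with open(path, "w") as fh:
        fh.write("# source\ttarget\n")
        for u, v in network.edge_list():
            fh.write(f"{u}\t{v}\n")


def largest_connected_component(network: Network) -> Network:
    """Restrict to the largest connected component (explicit, never implicit)."""
    g = network.to_networkx()
    import networkx as nx

    comp = max(nx.connected_components(g), key=len)
    if len(comp) == network.n_nodes:
        return network
    keep = sorted(comp)
    idx = [network.node_ids.index(x) for x in keep]
    return Network(keep, network.adjacency[np.ix_(idx, idx)])


def compute_ppmi(network: Network, walk_length: int = 10,
                 log_base: float | None = None) -> PPMIMatrix:
    """Closed-form random-walk PPMI matrix of a network.

    Parameters
    ----------
    network : Network
        Every node must have degree >= 1 (the degree matrix must be
        invertible).
    walk_length : int
        Random-walk length ``T`` (default 10).
    log_base : float, optional
        Base of the logarithm; defaults to the module constant
        (natural log).

    Returns
    -------
    PPMIMatrix
        Entrywise ``max{0, log(vol(N) * mean of the first T transition
        powers)}``.
    """
    if walk_length < 1:
        raise ValueError("walk_length must be >= 1")
    deg = network.degrees
    if np.any(deg == 0):
        bad = [network.node_ids[i] for i in np.nonzero(deg == 0)[0]]
        raise ValueError(f"isolated nodes make D singular: {bad[:5]}")
    base = LOG_BASE if log_base is None else log_base
    P_t = network.adjacency / deg[:, None]        # D^-1 A, row-stochastic
    power = np.eye(network.n_nodes)
    acc = np.zeros_like(P_t)
    for _ in range(walk_length):
        power = power @ P_t
        acc += power
    m = network.volume * acc / walk_length
    with np.errstate(divide="ignore"):
        logm = np.log(m, out=np.full_like(m, -np.inf), where=m > 0)
    if base != math.e:
        logm = logm / math.log(base)
    return PPMIMatrix(np.maximum(0.0, logm), walk_length, network)


def drop_edges(network: Network, fraction: float, seed: int) -> Network:
    """Remove ``floor(fraction * |E|)`` edges uniformly at random.

    Used by the edge-dropout robustness harness.  Removals that would
    isolate a node are resampled; if no valid removal set is found the
    call errors.
    """
    if not 0 <= fraction < 1:
        raise ValueError("fraction must be in [0, 1)")
    edges = network.edge_list()
    n_drop = int(fraction * len(edges))
    if n_drop == 0:
        return Network(list(network.node_ids), network.adjacency.copy())
    rng = np.random.default_rng(seed)
    for _ in range(200):
        drop = set(rng.choice(len(edges), n_drop, replace=False).tolist())
        kept = [e for i, e in enumerate(edges) if i not in drop]
        deg: dict[str, int] = {g: 0 for g in network.node_ids}
        for u, v in kept:
            deg[u] += 1
            deg[v] += 1
        if all(d >= 1 for d in deg.values()):
            A = np.zeros_like(network.adjacency)
            index = {g: i for i, g in enumerate(network.node_ids)}
            for u, v in kept:
                A[index[u], index[v]] = A[index[v], index[u]] = 1.0
            return Network(list(network.node_ids), A)
    raise ValueError(
        f"could not drop {n_drop} edges without isolating a node")
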