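"""Shared fixtures: toy graphs and the planted synthetic study.

The planted study uses the generator defaults (300 genes, 8 assortative
modules, 8 leaf terms per module annotating half their module) and is
computed once per session; individual tests slice what they need.
"""

import numpy as np
import pytest

import axesbio as ab


@pytest.fixture(scope="session")
def planted():
    """Full synthetic study at generator defaults (seed 0)."""
    spec = ab.SyntheticSpec()
    network, labels = ab.make_network(spec)
    dag, table, texts, term_module = ab.make_ontology_and_annotations(
        spec, labels)
    table = table.aligned_to(network.node_ids)
    return {"spec": spec, "network": network, "labels": labels,
            "dag": dag, "table": table, "texts": texts,
            "term_module": term_module}


@pytest.fixture(scope="session")
def ppmi300(planted):
    return ab.compute_ppmi(planted["network"])


@pytest.fixture(scope="session")
def onmtf8(ppmi300):
    return ab.NMTF(ppmi300, rank=8, orthonormal=True).fit()


@pytest.fixture(scope="session")
def annotated(planted, onmtf8):
    """Axis annotation of the planted study at n_perm=1000."""
    return ab.AxisAnnotator.from_decomposition(
        planted["table"], onmtf8).fit(n_perm=1000, seed=0)


@pytest.fixture()
def triangle():
    return ab.Network.from_edges([("a", "b"), ("b", "c"), ("a", "c")])


@pytest.fixture()
def single_edge():
    return ab.Network.from_edges([("g1", "g2")])


def brute_force_ppmi(adjacency: np.ndarray, walk_length: int) -> np.ndarray:
    """Independent dense evaluation of the random-walk PPMI closed form."""
    A = np.asarray(adjacency, dtype=float)
    D_inv = np.diag(1.0 / A.sum(axis=1))
    acc = np.zeros_like(A)
    for r in range(1, walk_length + 1):
        acc += np.linalg.matrix_power(D_inv @ A, r)
    inner = A.sum() * acc / walk_length
    with np.errstate(divide="ignore"):
        return np.maximum(0.0, np.log(inner,
                                      out=np.full_like(inner, -np.inf),
                                      where=inner > 0))
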