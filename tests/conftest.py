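import numpy as np
import pytest

from netvuln.io_formats import ExpressionMatrix
from netvuln.netbuild import EvidenceSummary, RegulatoryNetwork


def make_network(pairs):
    """Network from bare (mirna, gene) pairs with dummy provenance."""
    return RegulatoryNetwork(
        edges={(m, g): EvidenceSummary(experimental_lt_dbs=frozenset({"db"}))
               for m, g in pairs}
    )


def random_network(rng, n_mirna=30, n_gene=100, p_edge=0.05):
    """Bernoulli bipartite network; independent of the synthdata generator."""
    mask = rng.random((n_mirna, n_gene)) < p_edge
    pairs = [
        (f"m{i}", f"g{j}")
        for i in range(n_mirna)
        for j in range(n_gene)
        if mask[i, j]
    ]
    return make_network(pairs)


def two_group_matrix(values_a, values_b, feature_ids=None):
    """ExpressionMatrix from per-group value arrays (features x samples)."""
    a = np.atleast_2d(np.asarray(values_a, float))
    b = np.atleast_2d(np.asarray(values_b, float))
    n_feat = a.shape[0]
    if feature_ids is None:
        feature_ids = [f"f{i}" for i in range(n_feat)]
    sample_ids = [f"a{j}" for j in range(a.shape[1])] + [
        f"b{j}" for j in range(b.shape[1])
    ]
    groups = {s: ("group_A" if s.startswith("a") else "group_B") for s in sample_ids}
    return ExpressionMatrix(
        feature_ids=list(feature_ids),
        sample_ids=sample_ids,
        values=np.hstack([a, b]),
        groups=groups,
    )


@pytest.fixture
def fig_typology_net():
    """The four-regulatory-type toy: G1 unique to M1, G5 co-regulated by
    M2/M3, TF G10 unique to M4."""
    return make_network([("M1", "G1"), ("M2", "G5"), ("M3", "G5"), ("M4", "G10")])


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
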