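import numpy as np
import pytest

from icam.graph_io import FeatureMatrix, LabelTable, Network


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def tiny_network():
    """Path graph a-b-c plus isolated node d."""
    return Network(node_ids=("a", "b", "c", "d"), edges=((0, 1), (1, 2)))


@pytest.fixture
def two_cliques():
    """Two disconnected homophilous 5-cliques with informative attributes.

    One labeled node per clique (indices 0 and 5); class 0 lives on the
    first clique, class 1 on the second.
    """
    ids = tuple(f"v{i}" for i in range(10))
    edges = []
    for base in (0, 5):
        for i in range(base, base + 5):
            for j in range(i + 1, base + 5):
                edges.append((i, j))
    net = Network(node_ids=ids, edges=tuple(edges))
    rg = np.random.default_rng(7)
    X = rg.normal(scale=0.3, size=(10, 3))
    X[:5, 0] += 4.0
    X[5:, 1] += 4.0
    Y = np.zeros((10, 2), dtype=np.int8)
    Y[:5, 0] = 1
    Y[5:, 1] = 1
    known = np.zeros(10, dtype=bool)
    known[[0, 5]] = True
    observed = LabelTable(Y=np.where(known[:, None], Y, 0), known_mask=known)
    truth = LabelTable(Y=Y, known_mask=np.ones(10, dtype=bool))
    return net, FeatureMatrix(values=X), observed, truth


def random_stochastic(rng, m):
    """Random strictly positive column-stochastic matrix."""
    P = rng.random((m, m)) + 1e-3
    return P / P.sum(axis=0, keepdims=True)


def random_prior_matrix(rng, m, c):
    """Random label-prior-like matrix: each column a distribution over nodes."""
    Q = np.zeros((m, c))
    for d in range(c):
        members = rng.choice(m, size=rng.integers(1, max(2, m // 2)), replace=False)
        Q[members, d] = 1.0 / members.size
    return Q
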