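import numpy as np
import pytest

from herbnet import BipartiteNetwork, SyntheticConfig, generate_paired_study


def make_net(weights, season="all"):
    """Network with auto labels p1..pN / h1..hM from a weight matrix."""
    w = np.asarray(weights)
    plants = tuple(f"p{i+1}" for i in range(w.shape[0]))
    herbs = tuple(f"h{j+1}" for j in range(w.shape[1]))
    return BipartiteNetwork(plants, herbs, w, season=season)


@pytest.fixture
def matching3():
    """Perfect matching of 3 plant-herbivore pairs."""
    return make_net(np.eye(3, dtype=int))


@pytest.fixture
def complete22():
    return make_net(np.ones((2, 2), dtype=int))


@pytest.fixture
def complete55():
    return make_net(np.ones((5, 5), dtype=int))


@pytest.fixture
def path_php():
    """Two plants sharing one herbivore: the length-2 indirect pathway motif."""
    return make_net([[1], [1]])


@pytest.fixture
def single_edge():
    return make_net([[5]])


@pytest.fixture(scope="session")
def default_study():
    """One paired synthetic study at the default (field-mimicking) conditions."""
    return generate_paired_study(SyntheticConfig(seed=20260926))


def random_bipartite_adjacency(rng, max_nodes=40, p=0.3):
    """Random block adjacency of a bipartite graph with N <= max_nodes."""
    n_p = int(rng.integers(1, max_nodes // 2))
    n_h = int(rng.integers(1, max_nodes - n_p))
    B = (rng.random((n_p, n_h)) < p).astype(np.int64)
    if not B.any():
        B[rng.integers(n_p), rng.integers(n_h)] = 1
    n = n_p + n_h
    A = np.zeros((n, n), dtype=np.int64)
    A[:n_p, n_p:] = B
    A[n_p:, :n_p] = B.T
    return A
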