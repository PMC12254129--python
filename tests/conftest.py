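import numpy as np
import pytest

import ghnn


@pytest.fixture(scope="session")
def tiny_bundle():
    """A small mixed-signal bundle shared by read-only tests."""
    bundle, truth = ghnn.generate(ghnn.default_spec(
        n_nodes=60, n_features=8, n_signal_features=4, n_hyperedges=10,
        n_seed_nodes=4, seed=11))
    return bundle, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_graph(rng, n=8, p=0.4):
    """Erdos-Renyi GeneGraph for oracle comparisons."""
    edges = {(i, j) for i in range(n) for j in range(i + 1, n)
             if rng.random() < p}
    return ghnn.GeneGraph([f"n{i}" for i in range(n)], edges)


def random_hypergraph(rng, n=10, m=6, max_size=5, weights=False):
    hyperedges = []
    w = []
    for k in range(m):
        size = int(rng.integers(1, min(max_size, n) + 1))
        members = rng.choice(n, size=size, replace=False)
        hyperedges.append((f"he{k}", frozenset(int(x) for x in members)))
        w.append(float(rng.uniform(0.5, 2.0)) if weights else 1.0)
    return ghnn.PathwayHypergraph([f"n{i}" for i in range(n)], hyperedges, w)
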