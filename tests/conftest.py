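import numpy as np
import pytest

from mcesdist import random_molecular_graph, toy_library


@pytest.fixture(scope="session")
def toys():
    return toy_library()


def graphs_with_edges(n_graphs: int, seed: int, min_edges: int = 4,
                      max_edges: int = 7):
    """Seeded stream of random graphs whose edge counts lie in a range."""
    rng = np.random.default_rng(seed)
    out = []
    while len(out) < n_graphs:
        n = int(rng.integers(4, 9))
        g = random_molecular_graph(n, seed=int(rng.integers(2**31)),
                                   extra_edge_factor=0.3)
        if min_edges <= g.n_edges <= max_edges:
            out.append(g)
    return out


@pytest.fixture(scope="session")
def small_pairs():
    """200 seeded random pairs with 4-7 edges per graph, oracle-sized."""
    graphs = graphs_with_edges(400, seed=2024)
    return [(graphs[2 * i], graphs[2 * i + 1]) for i in range(200)]
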