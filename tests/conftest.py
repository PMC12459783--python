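import numpy as np
import pytest

from carst.rates_smr import CountPanel, expected_counts
from carst.synthetic_data import grid_graph


@pytest.fixture
def path3():
    from carst.areal_graph import graph_from_edges

    return graph_from_edges([(0, 1), (1, 2)], 3)


@pytest.fixture
def cycle4():
    from carst.areal_graph import graph_from_edges

    return graph_from_edges([(0, 1), (1, 2), (2, 3), (3, 0)], 4)


@pytest.fixture
def grid22():
    return grid_graph(2, 2)


@pytest.fixture
def small_panel():
    """8 areas x 4 years with modest Poisson-ish counts and E filled."""
    rng = np.random.default_rng(42)
    n, T = 8, 4
    P = np.full((n, T), 10_000.0)
    Y = rng.poisson(5.0, (n, T))
    panel = CountPanel(areas=tuple(f"a{i}" for i in range(n)),
                       years=tuple(range(2000, 2000 + T)), Y=Y, P=P)
    return expected_counts(panel)


def random_connected_graph(n: int, rng) -> "SpatialGraph":
    """Random spanning tree plus extra edges (always connected)."""
    from carst.areal_graph import graph_from_edges

    order = rng.permutation(n)
    edges = [(int(order[k]), int(order[rng.integers(0, k)]))
             for k in range(1, n)]
    extra = rng.integers(0, n, size=(n, 2))
    edges += [(int(a), int(b)) for a, b in extra if a != b]
    return graph_from_edges(edges, n)
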