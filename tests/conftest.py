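import numpy as np
import pytest

import patchboot as pb


@pytest.fixture
def rng():
    return np.random.default_rng(20170719)


@pytest.fixture(scope="session")
def fixture_graph_23():
    """A fixed 23-vertex connected graph used in small-sample tests."""
    rng = np.random.default_rng(23)
    model = pb.ztp(2)
    while True:
        g = pb.generate_graph(model, 23, rng)
        if g.degrees.min() >= 1:
            return g


@pytest.fixture(scope="session")
def ztp_graph_2000():
    """One zero-truncated-Poisson(2) graph of order 2000 (shared, read-only)."""
    rng = np.random.default_rng(2000)
    return pb.generate_graph(pb.ztp(2), 2000, rng)


@pytest.fixture
def path_graph():
    """The path 0-1-2-3."""
    return pb.SimpleGraph.from_edges(4, [(0, 1), (1, 2), (2, 3)])


@pytest.fixture
def triangle():
    return pb.SimpleGraph.from_edges(3, [(0, 1), (0, 2), (1, 2)])
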