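import networkx as nx
import numpy as np
import pytest

from raidsim import SocialNetwork, SimulationConfig, get_fixture


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def ring10():
    """Ring lattice, N=10, k=4 (zero rewiring)."""
    return SocialNetwork(nx.watts_strogatz_graph(10, 4, 0.0, seed=0))


@pytest.fixture
def path4():
    """Path graph 0-1-2-3."""
    return SocialNetwork(nx.path_graph(4))


@pytest.fixture
def star20():
    """Star graph: center 0, 19 leaves."""
    return SocialNetwork(nx.star_graph(19))


@pytest.fixture(scope="session")
def ws91():
    return get_fixture("ws91")


@pytest.fixture(scope="session")
def ws200():
    return get_fixture("ws200")


@pytest.fixture
def small_cfg():
    """Fast-converging config for unit-level simulation tests."""
    return SimulationConfig(n=3, m=3, stall_window=20, max_generations=500)
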