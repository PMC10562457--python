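import networkx as nx
import pytest

from netspine import datasets


@pytest.fixture(scope="session")
def lesmis() -> nx.Graph:
    return datasets.les_miserables()


@pytest.fixture()
def small_integer_graph() -> nx.Graph:
    """Connected 8-node graph with integer weights, no isolated nodes."""
    return datasets.random_weighted(8, 0.5, "integer", seed=3, connected=True)


@pytest.fixture()
def distinct_weight_graph() -> nx.Graph:
    """Connected 12-node graph with pairwise-distinct weights."""
    return datasets.random_weighted(12, 0.4, "uniform", seed=7, distinct=True, connected=True)
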