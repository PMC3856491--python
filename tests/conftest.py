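import networkx as nx
import numpy as np
import pytest

from gepess.io import InteractionNetwork
from gepess.synthetic import SyntheticSpec, generate_dataset


@pytest.fixture(scope="session")
def dataset():
    """The default desk-scale synthetic dataset (500 proteins, planted
    essentiality signal)."""
    return generate_dataset(SyntheticSpec())


@pytest.fixture(scope="session")
def labels_series(dataset):
    return dataset.labels.to_series()


def random_network(n: int, p: float, seed: int) -> InteractionNetwork:
    """Erdos-Renyi test graph with string node IDs (possibly disconnected)."""
    g = nx.gnp_random_graph(n, p, seed=seed)
    return InteractionNetwork(nx.relabel_nodes(g, {v: f"N{v:02d}" for v in g.nodes}))


# small named graphs used across feature tests
def k3() -> InteractionNetwork:
    return InteractionNetwork.from_edges([("A", "B"), ("B", "C"), ("A", "C")])


def path3() -> InteractionNetwork:
    return InteractionNetwork.from_edges([("A", "B"), ("B", "C")])


def star3() -> InteractionNetwork:
    return InteractionNetwork.from_edges([("S", "L1"), ("S", "L2"), ("S", "L3")])


def k4() -> InteractionNetwork:
    nodes = ["A", "B", "C", "D"]
    return InteractionNetwork.from_edges(
        [(u, v) for i, u in enumerate(nodes) for v in nodes[i + 1:]])
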