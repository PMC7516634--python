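import numpy as np
import pytest

import motifemerge as me


class ScriptedRNG:
    """Plays back a fixed sequence of uniform draws, then a constant.

    Lets the deterministic branches of the tree generator be exercised
    without monkeypatching NumPy.
    """

    def __init__(self, values, fill=0.4):
        self.values = list(values)
        self.fill = fill

    def random(self):
        return self.values.pop(0) if self.values else self.fill


@pytest.fixture
def scripted_rng():
    return ScriptedRNG


@pytest.fixture(scope="session")
def tree_dataset():
    """4,000-sample tree environment at the reference settings."""
    return me.generate_tree_dataset(me.TreeConfig(n_samples=4000, seed=7))


@pytest.fixture(scope="session")
def clusters_dataset():
    """4,000-sample independent-clusters environment."""
    return me.generate_clusters_dataset(me.ClustersConfig(n_samples=4000, seed=3))


@pytest.fixture(scope="session")
def arch_240120():
    return me.MLPArchitecture.from_preset("240120")


def random_digraph(n_nodes, p, rng):
    """Simple random digraph without self-loops."""
    import networkx as nx

    g = nx.DiGraph()
    g.add_nodes_from(range(n_nodes))
    for i in range(n_nodes):
        for j in range(n_nodes):
            if i != j and rng.random() < p:
                g.add_edge(i, j)
    return g
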