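import networkx as nx
import numpy as np
import pandas as pd
import pytest

from colitiskit.microbiome import FeatureTable


@pytest.fixture
def k4_pendant():
    """K4 on 1..4 plus a pendant node 5 attached to node 1."""
    g = nx.complete_graph([1, 2, 3, 4])
    g.add_edge(1, 5)
    return g


@pytest.fixture
def planted_clique_graph():
    """ER(200, 0.03) with a 12-clique planted on nodes 0..11 (seed 1)."""
    g = nx.gnp_random_graph(200, 0.03, seed=1)
    for i in range(12):
        for j in range(i + 1, 12):
            g.add_edge(i, j)
    g.remove_nodes_from(list(nx.isolates(g)))
    return g, set(range(12))


@pytest.fixture
def small_table():
    counts = pd.DataFrame(
        [[10, 5, 0, 1], [8, 6, 1, 0], [0, 2, 9, 9], [1, 1, 10, 8]],
        index=["a1", "a2", "b1", "b2"],
        columns=["f1", "f2", "f3", "f4"],
    )
    groups = pd.Series(["A", "A", "B", "B"], index=counts.index)
    taxonomy = pd.Series(
        [
            "k__Bacteria;p__P1;c__;o__;f__;g__G1",
            "k__Bacteria;p__P1;c__;o__;f__;g__G2",
            "k__Bacteria;p__P2;c__;o__;f__;g__G3",
            "k__Bacteria;p__P2;c__;o__;f__;g__G3",
        ],
        index=counts.columns,
    )
    return FeatureTable(counts, groups, taxonomy)


def random_connected_graph(rng: np.random.Generator, n_max: int = 30) -> nx.Graph:
    for _ in range(100):
        n = int(rng.integers(5, n_max + 1))
        p = float(rng.uniform(0.1, 0.4))
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        if g.number_of_edges() and nx.is_connected(g):
            return g
    raise RuntimeError("could not sample a connected graph")
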