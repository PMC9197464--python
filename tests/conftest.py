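import networkx as nx
import numpy as np
import pytest

from prnet.coexpression import WeightedNetwork


@pytest.fixture
def write_tsv(tmp_path):
    """Write rows (sequences of strings) as a TSV file and return its path."""
    def _write(name, rows):
        path = tmp_path / name
        path.write_text("".join("\t".join(row) + "\n" for row in rows))
        return path
    return _write


def unit_network(edges) -> WeightedNetwork:
    """WeightedNetwork with unit weights from an iterable of pairs."""
    G = nx.Graph()
    for a, b in edges:
        G.add_edge(str(a), str(b), weight=1.0, signed_corr=1.0)
    return WeightedNetwork(G)


def random_weighted_network(rng: np.random.Generator, n: int, p: float
                            ) -> WeightedNetwork:
    """Random Gnp graph with random weights in (0, 1]; isolated nodes pruned."""
    G = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31 - 1)))
    H = nx.Graph()
    for u, v in G.edges:
        H.add_edge(f"n{u}", f"n{v}", weight=float(rng.uniform(0.05, 1.0)),
                   signed_corr=1.0)
    return WeightedNetwork(H)


@pytest.fixture
def bridged_triangles():
    """Two triangles joined by a single bridge edge, unit weights."""
    return unit_network([("a", "b"), ("b", "c"), ("a", "c"),
                         ("d", "e"), ("e", "f"), ("d", "f"), ("c", "d")])
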