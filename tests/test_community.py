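"""Walktrap community detection: walk distances, merges, modularity cuts."""

import networkx as nx
import numpy as np
import pytest

from prnet.community import (CommunityPartition, WalktrapParams,
                             cut_assignment, delta_sigma, modularity,
                             transition_probabilities, walktrap)
from prnet.exceptions import InputError

from conftest import random_weighted_network, unit_network


def all_set_partitions(items):
    """Enumerate every partition of a small set (Bell-number many)."""
    items = list(items)
    if not items:
        yield []
        return
    head, rest = items[0], items[1:]
    for part in all_set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [part[i] + [head]] + part[i + 1:]
        yield part + [[head]]


def partition_to_assignment(blocks):
    return {v: i for i, block in enumerate(blocks) for v in block}


class TestTransitionProbabilities:
    def test_single_edge_one_step_forces_move(self):
        net = unit_network([("A", "B")])
        nodes, Pt = transition_probabilities(net, steps=1)
        a = nodes.index("A")
        assert Pt[a, nodes.index("B")] == pytest.approx(1.0)

    def test_single_edge_two_steps_bounces_back(self):
        net = unit_network([("A", "B")])
        nodes, Pt = transition_probabilities(net, steps=2)
        a = nodes.index("A")
        assert Pt[a, a] == pytest.approx(1.0)

    def test_triangle_two_step_enumeration(self):
        """2-step paths on K3: return home w.p. 1/2, each neighbour 1/4."""
        net = unit_network([("A", "B"), ("B", "C"), ("A", "C")])
        nodes, Pt = transition_probabilities(net, steps=2)
        a = nodes.index("A")
        assert Pt[a, a] == pytest.approx(0.5)
        assert Pt[a, nodes.index("B")] == pytest.approx(0.25)
        assert Pt[a, nodes.index("C")] == pytest.approx(0.25)

    @pytest.mark.parametrize("seed", range(4))
    def test_rows_are_distributions(self, seed):
        rng = np.random.default_rng(seed)
        net = random_weighted_network(rng, 12, 0.4)
        _, Pt = transition_probabilities(net, steps=4)
        assert np.allclose(Pt.sum(axis=1), 1.0, atol=1e-12)
        assert (Pt >= -1e-15).all()

    def test_isolated_node_is_fatal(self):
        G = nx.Graph()
        G.add_edge("A", "B", weight=1.0)
        G.add_node("L")
        with pytest.raises(InputError, match="isolated"):
            transition_probabilities(G, steps=2)


class TestModularity:
    def test_single_community_is_zero(self, bridged_triangles):
        assignment = {v: 0 for v in bridged_triangles.graph.nodes}
        assert modularity(bridged_triangles, assignment) == pytest.approx(0.0)

    def test_two_disjoint_triangles_is_half(self):
        net = unit_network([("a", "b"), ("b", "c"), ("a", "c"),
                            ("x", "y"), ("y", "z"), ("x", "z")])
        assignment = {"a": 0, "b": 0, "c": 0, "x": 1, "y": 1, "z": 1}
        assert modularity(net, assignment) == pytest.approx(0.5, abs=1e-12)

    def test_singleton_partition_is_negative(self, bridged_triangles):
        assignment = {v: i for i, v in
                      enumerate(bridged_triangles.graph.nodes)}
        G = bridged_triangles.graph
        m = G.size(weight="weight")
        expected = -sum((G.degree(v, weight="weight") / (2 * m)) ** 2
                        for v in G.nodes)
        q = modularity(bridged_triangles, assignment)
        assert q == pytest.approx(expected, abs=1e-12)
        assert q < 0

    def test_missing_node_is_fatal(self, bridged_triangles):
        with pytest.raises(InputError, match="missing"):
            modularity(bridged_triangles, {"a": 0})

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_networkx(self, seed):
        """Independent cross-check against networkx's weighted modularity."""
        rng = np.random.default_rng(seed)
        net = random_weighted_network(rng, 15, 0.3)
        nodes = list(net.graph.nodes)
        labels = rng.integers(0, 3, size=len(nodes))
        assignment = {v: int(l) for v, l in zip(nodes, labels)}
        groups = [{v for v in nodes if assignment[v] == c}
                  for c in set(labels)]
        expected = nx.community.modularity(net.graph, groups, weight="weight")
        assert modularity(net, assignment) == pytest.approx(expected,
                                                            abs=1e-12)


class TestWalktrap:
    def test_bridged_triangles_split_into_triangles(self, bridged_triangles):
        part = walktrap(bridged_triangles)
        comms = {frozenset(c) for c in part.communities().values()}
        assert comms == {frozenset("abc"), frozenset("def")}

    def test_bridged_triangles_cut_beats_all_other_cuts(self, bridged_triangles):
        """The returned cut maximizes modularity over every dendrogram prefix."""
        part = walktrap(bridged_triangles)
        qs = [modularity(bridged_triangles,
                         cut_assignment(bridged_triangles,
                                        part.merge_sequence, k))
              for k in range(len(part.modularity_trace))]
        assert part.best_modularity == pytest.approx(max(qs), abs=1e-12)

    def test_k4_collapses_to_one_community(self):
        net = unit_network([(i, j) for i in range(4) for j in range(i + 1, 4)])
        part = walktrap(net)
        assert part.n_communities == 1
        # exhaustive: no partition of K4 has modularity above 0
        best = max(modularity(net, partition_to_assignment(p))
                   for p in all_set_partitions(net.graph.nodes))
        assert part.best_modularity == pytest.approx(best, abs=1e-12)
        assert best == pytest.approx(0.0, abs=1e-12)

    def test_disconnected_cliques_never_mix(self):
        net = unit_network([("a", "b"), ("b", "c"), ("a", "c"),
                            ("x", "y"), ("y", "z"), ("x", "z")])
        part = walktrap(net)
        for members in part.communities().values():
            assert members <= {"a", "b", "c"} or members <= {"x", "y", "z"}

    @pytest.mark.parametrize("seed", range(8))
    def test_trace_matches_cut_modularity_and_best_is_max(self, seed):
        """Incremental modularity bookkeeping equals direct evaluation at
        every dendrogram prefix, and best_modularity is the prefix maximum."""
        rng = np.random.default_rng(100 + seed)
        net = random_weighted_network(rng, int(rng.integers(5, 9)), 0.5)
        if net.graph.number_of_edges() == 0:
            pytest.skip("degenerate empty graph")
        part = walktrap(net)
        qs = [modularity(net, cut_assignment(net, part.merge_sequence, k))
              for k in range(len(part.modularity_trace))]
        assert np.allclose(part.modularity_trace, qs, atol=1e-12)
        assert part.best_modularity == pytest.approx(max(qs), abs=1e-12)

    @pytest.mark.parametrize("seed", range(6))
    def test_each_merge_minimizes_direct_delta_sigma(self, seed):
        """Replay the merge sequence, recomputing every adjacent-pair distance
        from the walk distributions (O(n^2) oracle): each merged pair must
        have had minimal delta-sigma among adjacent pairs at its step."""
        rng = np.random.default_rng(200 + seed)
        net = random_weighted_network(rng, 10, 0.4)
        if net.graph.number_of_edges() < 2:
            pytest.skip("too few edges")
        part = walktrap(net, WalktrapParams(steps=4))
        G = net.graph
        nodes = list(G.nodes)
        index = {v: i for i, v in enumerate(nodes)}
        W = nx.to_numpy_array(G, nodelist=nodes, weight="weight")
        d = W.sum(axis=1)
        inv_d = 1.0 / d
        Pt = np.linalg.matrix_power(W / d[:, None], 4)
        n = len(nodes)
        members = {i: {i} for i in range(n)}
        for a, b, c in part.merge_sequence:
            # oracle: direct delta-sigma for every currently adjacent pair
            adj = {}
            ids = sorted(members)
            for ii, p in enumerate(ids):
                for q in ids[ii + 1:]:
                    touching = any(
                        W[x, y] > 0 for x in members[p] for y in members[q])
                    if touching:
                        dp = Pt[sorted(members[p])].mean(axis=0)
                        dq = Pt[sorted(members[q])].mean(axis=0)
                        adj[(p, q)] = delta_sigma(dp, dq, inv_d,
                                                  len(members[p]),
                                                  len(members[q]), n)
            key = (a, b) if a < b else (b, a)
            assert key in adj
            assert adj[key] == pytest.approx(min(adj.values()), abs=1e-12)
            members[c] = members.pop(a) | members.pop(b)

    @pytest.mark.parametrize("seed", range(10))
    def test_communities_never_span_components(self, seed):
        rng = np.random.default_rng(300 + seed)
        net = random_weighted_network(rng, 20, 0.12)
        if net.graph.number_of_edges() == 0:
            pytest.skip("empty graph")
        part = walktrap(net)
        comp_of = {}
        for ci, comp in enumerate(nx.connected_components(net.graph)):
            for v in comp:
                comp_of[v] = ci
        for members in part.communities().values():
            assert len({comp_of[v] for v in members}) == 1

    def test_deterministic_across_reruns(self):
        rng = np.random.default_rng(42)
        net = random_weighted_network(rng, 25, 0.2)
        p1 = walktrap(net)
        p2 = walktrap(net)
        assert p1.assignment == p2.assignment
        assert p1.merge_sequence == p2.merge_sequence
        assert p1.modularity_trace == p2.modularity_trace

    def test_agrees_with_igraph_on_clear_structure(self, bridged_triangles):
        """Independent reference: igraph's walktrap finds the same split."""
        igraph = pytest.importorskip("igraph")
        G = bridged_triangles.graph
        nodes = list(G.nodes)
        idx = {v: i for i, v in enumerate(nodes)}
        g = igraph.Graph(
            n=len(nodes),
            edges=[(idx[u], idx[v]) for u, v in G.edges],
        )
        ref = g.community_walktrap(steps=4).as_clustering()
        ref_comms = {frozenset(nodes[i] for i in c) for c in ref}
        ours = {frozenset(c) for c in
                walktrap(bridged_triangles).communities().values()}
        assert ours == ref_comms

    def test_empty_network_is_fatal(self):
        with pytest.raises(InputError, match="empty"):
            walktrap(nx.Graph())

    def test_invalid_steps_rejected(self):
        with pytest.raises(InputError):
            WalktrapParams(steps=0)
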