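import networkx as nx
import numpy as np
import pytest

from ncycnet import (
    avg_path_length,
    communities_edge_betweenness,
    density,
    node_centralities,
    stats_report,
    transitivity_global,
)
from conftest import random_graph
from oracles import (
    avg_path_length_brute,
    betweenness_brute,
    closeness_brute,
    density_brute,
    transitivity_brute,
)


class TestDensity:
    def test_complete_graph(self):
        assert density(nx.complete_graph(4)) == pytest.approx(1.0)

    def test_path_on_four_nodes(self):
        assert density(nx.path_graph(4)) == pytest.approx(0.5)

    def test_dyad(self):
        assert density(nx.path_graph(2)) == pytest.approx(1.0)

    def test_single_node_rejected(self):
        g = nx.Graph()
        g.add_node("A")
        with pytest.raises(ValueError):
            density(g)


class TestTransitivity:
    def test_triangle(self):
        assert transitivity_global(nx.complete_graph(3)) == pytest.approx(1.0)

    def test_star_has_no_triangles(self):
        assert transitivity_global(nx.star_graph(3)) == pytest.approx(0.0)

    def test_k4_minus_an_edge(self):
        g = nx.complete_graph(4)
        g.remove_edge(0, 1)
        assert transitivity_global(g) == pytest.approx(0.75)


class TestAvgPathLength:
    def test_complete_graph(self):
        assert avg_path_length(nx.complete_graph(5)) == pytest.approx(1.0)

    def test_path_of_three(self):
        assert avg_path_length(nx.path_graph(3)) == pytest.approx(4 / 3)

    def test_disconnected_counts_reachable_pairs_only(self):
        g = nx.Graph([("A", "B"), ("C", "D")])
        assert avg_path_length(g) == pytest.approx(1.0)

    def test_edgeless_rejected(self):
        g = nx.Graph()
        g.add_nodes_from("AB")
        with pytest.raises(ValueError):
            avg_path_length(g)


class TestCentralities:
    def test_star_center_routes_all_pairs(self):
        g = nx.star_graph(4)  # center 0, leaves 1..4
        cent = node_centralities(g)
        assert cent.loc[0, "betweenness"] == pytest.approx(6.0)
        assert all(cent.loc[leaf, "betweenness"] == 0 for leaf in range(1, 5))

    def test_path_of_three_by_hand(self):
        cent = node_centralities(nx.path_graph(3))  # 0-1-2
        assert cent.loc[1, "betweenness"] == pytest.approx(1.0)
        assert cent.loc[1, "closeness"] == pytest.approx(0.5)
        assert cent.loc[1, "normalized_degree"] == pytest.approx(1.0)
        assert cent.loc[0, "closeness"] == pytest.approx(1 / 3)

    def test_triangle_all_zero_betweenness(self):
        cent = node_centralities(nx.complete_graph(3))
        assert (cent["betweenness"] == 0).all()

    def test_closeness_within_component(self):
        g = nx.Graph([("A", "B"), ("C", "D"), ("D", "E")])
        cent = node_centralities(g)
        assert cent.loc["A", "closeness"] == pytest.approx(1.0)
        assert cent.loc["D", "closeness"] == pytest.approx(1 / 2)
        assert cent.loc["C", "closeness"] == pytest.approx(1 / 3)


class TestOracleEquivalence:
    """Brute-force cross-checks on random graphs with n <= 8."""

    def test_statistics_match_brute_force(self):
        rng = np.random.default_rng(2024)
        for _ in range(60):
            g = random_graph(rng)
            nodes, edges = list(g.nodes), list(g.edges)
            assert density(g) == pytest.approx(density_brute(nodes, edges))
            assert transitivity_global(g) == pytest.approx(transitivity_brute(nodes, edges))
            assert avg_path_length(g) == pytest.approx(avg_path_length_brute(nodes, edges))
            cent = node_centralities(g)
            bb = betweenness_brute(nodes, edges)
            cb = closeness_brute(nodes, edges)
            for v in nodes:
                assert cent.loc[v, "betweenness"] == pytest.approx(bb[v], abs=1e-9)
                assert cent.loc[v, "closeness"] == pytest.approx(cb[v], abs=1e-12)
                assert cent.loc[v, "normalized_degree"] == pytest.approx(g.degree(v) / (len(nodes) - 1))

    def test_bounds_and_dense_regime(self):
        rng = np.random.default_rng(7)
        for _ in range(40):
            g = random_graph(rng)
            c = transitivity_global(g)
            L = avg_path_length(g)
            assert 0.0 <= c <= 1.0
            assert L >= 1.0
            if nx.is_connected(g):
                p = density(g)
                assert L >= 2 - p - 1e-12
                if nx.diameter(g) <= 2:
                    assert L == pytest.approx(2 - p)


class TestCommunities:
    def test_bridged_triangles_split_in_two(self, toy_network):
        modules, count = communities_edge_betweenness(toy_network)
        assert count == 2
        assert {frozenset(m) for m in modules} == {frozenset("abc"), frozenset("def")}

    def test_edgeless_nodes_are_singletons(self):
        g = nx.Graph()
        g.add_nodes_from("ABC")
        modules, count = communities_edge_betweenness(g)
        assert count == 3
        assert all(len(m) == 1 for m in modules)

    def test_complete_graph_single_module(self):
        modules, count = communities_edge_betweenness(nx.complete_graph(4))
        assert count == 1
        assert modules[0] == {0, 1, 2, 3}

    def test_modules_never_span_components(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            g = random_graph(rng)
            modules, _ = communities_edge_betweenness(g)
            comps = list(nx.connected_components(g))
            assert {frozenset().union(*[frozenset(m) for m in modules])} == {frozenset(g.nodes)}
            for m in modules:
                assert any(m <= comp for comp in comps)

    def test_deterministic(self, toy_network):
        first = communities_edge_betweenness(toy_network)
        second = communities_edge_betweenness(toy_network)
        assert first == second


class TestStatsReport:
    def test_complete_graph_limits(self):
        r = stats_report(nx.complete_graph(4))
        assert r.density == pytest.approx(1.0)
        assert r.clustering_coefficient == pytest.approx(1.0)
        assert r.avg_path_length == pytest.approx(1.0)
        assert r.n_modules == 1

    def test_path_graph(self):
        r = stats_report(nx.path_graph(4))
        assert r.density == pytest.approx(0.5)
        assert r.clustering_coefficient == pytest.approx(0.0)

    def test_too_small_network_rejected(self):
        g = nx.Graph()
        g.add_node("A")
        with pytest.raises(ValueError):
            stats_report(g)
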