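"""Node-level and global graph statistics against closed forms and oracles."""

import math

import numpy as np
import pytest

from metabonet import (
    MetabonetError,
    SimpleGraph,
    UndefinedMetricError,
    betweenness_centrality,
    closeness_centrality,
    eigenvector_centrality,
    global_metrics,
    harmonic_closeness,
    hits_authority_hub,
    metrics_table,
    rank_centrality,
    shortest_path_distances,
    triangles_and_clustering,
)
from metabonet.errors import ConfigurationError

from conftest import floyd_warshall_oracle, random_graph, to_networkx


def star(k=12):
    nodes = ["c"] + [f"l{i}" for i in range(k)]
    return SimpleGraph(nodes, [("c", leaf) for leaf in nodes[1:]])


def path3():
    return SimpleGraph("ABC", [("A", "B"), ("B", "C")])


def complete(n):
    nodes = [f"n{i}" for i in range(n)]
    return SimpleGraph(nodes, [(nodes[i], nodes[j])
                               for i in range(n) for j in range(i + 1, n)])


class TestSimpleGraph:
    def test_rejects_self_loops_duplicates_unknown_nodes(self):
        g = SimpleGraph("AB")
        with pytest.raises(MetabonetError):
            g.add_edge("A", "A")
        g.add_edge("A", "B", 0.5)
        with pytest.raises(MetabonetError):
            g.add_edge("B", "A")
        with pytest.raises(MetabonetError):
            g.add_edge("A", "Z")

    def test_adjacency_matrix_binary_vs_weighted(self):
        g = SimpleGraph("AB", [("A", "B", -0.4)])
        assert g.adjacency_matrix()[0, 1] == 1.0
        assert g.adjacency_matrix(weighted=True)[0, 1] == -0.4


class TestDistances:
    def test_path_and_complete_graph(self):
        d = shortest_path_distances(path3())
        assert d[0, 2] == 2
        d13 = shortest_path_distances(complete(13))
        assert np.all(d13[~np.eye(13, dtype=bool)] == 1)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_floyd_warshall(self, seed):
        g = random_graph(np.random.default_rng(seed))
        np.testing.assert_array_equal(shortest_path_distances(g), floyd_warshall_oracle(g))

    def test_unreachable_pairs_are_infinite(self):
        g = SimpleGraph("ABCD", [("A", "B"), ("C", "D")])
        d = shortest_path_distances(g)
        assert math.isinf(d[0, 2])


class TestClosenessAndHarmonic:
    def test_star_center_and_leaf(self):
        g = star(12)
        clo = closeness_centrality(g)
        assert clo["c"] == pytest.approx(1.0)
        assert clo["l0"] == pytest.approx(12 / 23)
        har = harmonic_closeness(g)
        assert har["c"] == pytest.approx(1.0)
        assert har["l0"] == pytest.approx(6.5 / 12)

    def test_path_end_node(self):
        assert closeness_centrality(path3())["A"] == pytest.approx(2 / 3)

    def test_disconnected_conventions(self):
        g = SimpleGraph("ABC", [("A", "B")])
        clo = closeness_centrality(g)
        har = harmonic_closeness(g)
        assert clo["C"] == 0.0                       # isolated node
        assert clo["A"] == pytest.approx(1.0)        # reachable set only
        assert har["A"] == pytest.approx(0.5)        # (1 + 0)/2, 1/inf = 0


class TestBetweenness:
    def test_path_middle_node(self):
        b = betweenness_centrality(path3())
        assert b == {"A": 0.0, "B": 1.0, "C": 0.0}

    def test_star_center_counts_all_leaf_pairs(self):
        assert betweenness_centrality(star(12))["c"] == pytest.approx(66.0)

    def test_four_cycle_splits_credit(self):
        g = SimpleGraph("ABCD", [("A", "B"), ("B", "C"), ("C", "D"), ("D", "A")])
        b = betweenness_centrality(g)
        assert all(v == pytest.approx(0.5) for v in b.values())

    def test_isolating_a_star_leaf_never_raises_others(self):
        # spot-check on the star: removing a leaf's edge lowers the
        # center's pair count and leaves the other leaves at zero
        g = star(12)
        before = betweenness_centrality(g)
        reduced = SimpleGraph(g.nodes, [(u, v) for u, v, _ in g.edge_list() if "l0" not in (u, v)])
        after = betweenness_centrality(reduced)
        for node in g.nodes:
            if node != "l0":
                assert after[node] <= before[node]


class TestSpectral:
    def test_complete_graph_is_flat(self):
        eig = eigenvector_centrality(complete(5))
        assert all(v == pytest.approx(1.0) for v in eig.values())

    def test_star_closed_form(self):
        eig = eigenvector_centrality(star(12))
        assert eig["c"] == pytest.approx(1.0)
        for i in range(12):
            assert eig[f"l{i}"] == pytest.approx(1 / math.sqrt(12), abs=1e-9)

    def test_hits_equals_eigenvector_ordering_and_l2_norm(self):
        g = star(12)
        hits = hits_authority_hub(g)
        auth = np.array([hits[u][0] for u in g.nodes])
        assert np.linalg.norm(auth) == pytest.approx(1.0)
        eig = eigenvector_centrality(g)
        assert max(hits, key=lambda u: hits[u][0]) == max(eig, key=eig.get)

    @pytest.mark.parametrize("seed", range(10))
    def test_authority_equals_hub_on_undirected_graphs(self, seed):
        g = random_graph(np.random.default_rng(100 + seed))
        for a, h in hits_authority_hub(g).values():
            assert abs(a - h) < 1e-3

    def test_edgeless_graph_is_undefined(self):
        with pytest.raises(UndefinedMetricError):
            eigenvector_centrality(SimpleGraph("ABC"))


class TestTrianglesClustering:
    def test_triangle_graph(self):
        g = SimpleGraph("ABC", [("A", "B"), ("B", "C"), ("A", "C")])
        assert triangles_and_clustering(g) == {"A": (1, 1.0), "B": (1, 1.0), "C": (1, 1.0)}

    def test_path_middle_node_zero(self):
        assert triangles_and_clustering(path3())["B"] == (0, 0.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_triple_enumeration(self, seed):
        g = random_graph(np.random.default_rng(200 + seed), n_max=12)
        result = triangles_and_clustering(g)
        for u in g.nodes:
            tri = sum(
                1
                for i, a in enumerate(g.adj[u])
                for b in g.adj[u][i + 1:]
                if g.has_edge(a, b)
            )
            deg = g.degree(u)
            coeff = tri / (deg * (deg - 1) / 2) if deg >= 2 else 0.0
            assert result[u] == (tri, pytest.approx(coeff))


class TestGlobalMetrics:
    def test_density_identities_on_13_nodes(self):
        for m, expected in ((28, 28 / 78), (34, 34 / 78)):
            g = complete(13)
            edges = g.edge_list()[:m]
            gm = global_metrics(SimpleGraph(g.nodes, edges))
            assert gm.density == pytest.approx(expected)
            assert gm.density * 78 == pytest.approx(gm.edge_count)

    def test_path_graph_diameter_and_average_path(self):
        gm = global_metrics(path3())
        assert gm.diameter == 2
        assert gm.average_path_length == pytest.approx(4 / 3)

    def test_disconnected_uses_finite_distances_only(self):
        g = SimpleGraph("ABCD", [("A", "B"), ("B", "C")])
        gm = global_metrics(g)
        assert gm.diameter == 2
        assert gm.average_path_length == pytest.approx((1 + 1 + 2) / 3)

    def test_edgeless_graph_undefined(self):
        with pytest.raises(UndefinedMetricError):
            global_metrics(SimpleGraph("ABC"))

    def test_average_path_length_bounded_by_diameter(self):
        for seed in range(10):
            g = random_graph(np.random.default_rng(300 + seed), require_connected=True)
            if g.n < 2:
                continue
            gm = global_metrics(g)
            assert 1.0 <= gm.average_path_length <= gm.diameter


class TestClosenessIntegerRatioProperty:
    def test_closeness_is_ratio_of_12_to_integer_on_connected_13_node_graphs(self):
        for seed in range(20):
            g = random_graph(np.random.default_rng(400 + seed), n_min=13, n_max=13,
                             require_connected=True)
            for value in closeness_centrality(g).values():
                k = 12 / value
                assert k == pytest.approx(round(k), abs=1e-9)


class TestMetricsTableAndRanking:
    def test_complete_graph_rows_identical(self):
        table = metrics_table(complete(4))
        numeric = table.drop(columns=["node"])
        assert (numeric.nunique() == 1).all()

    def test_star_has_exactly_one_unit_eigenvector_row(self):
        table = metrics_table(star(12))
        assert len(table) == 13
        assert np.isclose(table["eigenvector"], 1.0).sum() == 1
        assert table["eigenvector"].max() == pytest.approx(1.0)

    def test_rank_centrality_star_and_ties(self):
        table = metrics_table(star(4))
        assert rank_centrality(table, "eigenvector")[0] == "c"
        tied = table.copy()
        tied["eigenvector"] = 0.5
        assert rank_centrality(tied, "eigenvector") == list(table["node"])

    def test_rank_strictly_descending_on_distinct_values(self):
        table = metrics_table(star(5))
        ranked = rank_centrality(table, "betweenness")
        values = table.set_index("node").loc[ranked, "betweenness"].tolist()
        assert values == sorted(values, reverse=True)

    def test_unknown_metric_rejected(self):
        with pytest.raises(ConfigurationError):
            rank_centrality(metrics_table(star(3)), "pagerank")


class TestNetworkxParity:
    """Cross-checks against the networkx oracle on random graphs."""

    @pytest.mark.parametrize("seed", range(25))
    def test_all_metrics_match(self, seed):
        import networkx as nx

        g = random_graph(np.random.default_rng(500 + seed))
        gx = to_networkx(g)
        clo = closeness_centrality(g)
        nx_clo = nx.closeness_centrality(gx, wf_improved=False)
        har = harmonic_closeness(g)
        nx_har = nx.harmonic_centrality(gx)
        bet = betweenness_centrality(g)
        nx_bet = nx.betweenness_centrality(gx, normalized=False, weight=None)
        tri = triangles_and_clustering(g)
        nx_tri = nx.triangles(gx)
        nx_clust = nx.clustering(gx)
        for u in g.nodes:
            assert clo[u] == pytest.approx(nx_clo[u], abs=1e-12)
            assert har[u] == pytest.approx(nx_har[u] / (g.n - 1), abs=1e-12)
            assert bet[u] == pytest.approx(nx_bet[u], abs=1e-9)
            assert tri[u][0] == nx_tri[u]
            assert tri[u][1] == pytest.approx(nx_clust[u], abs=1e-12)
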