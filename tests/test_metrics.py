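"""Network construction, centralities, density and walktrap clustering."""

import itertools

import networkx as nx
import numpy as np
import pytest
from scipy import stats

from socioscan.association import AssociationMatrix
from socioscan.metrics import (
    SocialNetwork,
    build_network,
    density,
    eigenvector_centrality,
    modularity_of_partition,
    node_metrics,
    walktrap_clusters,
)


def net_from_edges(edges, directed=False, context="forest", data_type="proximity"):
    g = nx.DiGraph() if directed else nx.Graph()
    g.add_weighted_edges_from(edges)
    return SocialNetwork(graph=g, context=context, data_type=data_type)


class TestBuildNetwork:
    def test_symmetric_matrix_gives_undirected_triangle(self):
        m = AssociationMatrix(["A", "B", "C"], "forest", "proximity", np.full((3, 3), 0.5) - 0.5 * np.eye(3))
        net = build_network(m)
        assert not net.directed
        assert net.graph.number_of_edges() == 3

    def test_zero_matrix_gives_edgeless_network(self):
        m = AssociationMatrix(["A", "B"], "forest", "proximity", np.zeros((2, 2)))
        assert build_network(m).graph.number_of_edges() == 0

    def test_asymmetric_affiliative_matrix_gives_directed_graph(self):
        hwi = np.array([[0, 0.4, 0], [0.1, 0, 0], [0, 0, 0]])
        net = build_network(AssociationMatrix(["A", "B", "C"], "road", "affiliative", hwi))
        assert net.directed
        assert net.graph["A"]["B"]["weight"] == pytest.approx(0.4)
        assert net.graph["B"]["A"]["weight"] == pytest.approx(0.1)


class TestDensity:
    def test_complete_triangle(self):
        assert density(net_from_edges([("A", "B", 1), ("B", "C", 1), ("A", "C", 1)])) == 1.0

    def test_undirected_partial(self):
        net = net_from_edges([("A", "B", 1), ("C", "D", 1)])
        assert density(net) == pytest.approx(2 / 6)

    def test_directed_counts_arcs(self):
        net = net_from_edges([("A", "B", 1), ("B", "A", 1)], directed=True)
        net.graph.add_node("C")
        assert density(net) == pytest.approx(2 / 6)

    def test_single_node_is_error(self):
        g = nx.Graph()
        g.add_node("A")
        with pytest.raises(ValueError, match="fewer than 2"):
            density(SocialNetwork(g, "forest", "proximity"))

    def test_removing_edge_never_increases_density_or_degree(self):
        net = net_from_edges([("A", "B", 0.5), ("B", "C", 0.3), ("A", "C", 0.2)])
        before_d = density(net)
        before_deg = node_metrics(net).table["weighted_degree"]
        net.graph.remove_edge("A", "B")
        after_d = density(net)
        after_deg = node_metrics(net).table["weighted_degree"]
        assert after_d <= before_d
        assert (after_deg <= before_deg + 1e-12).all()


class TestNodeMetrics:
    def test_unit_path_closed_forms(self):
        mt = node_metrics(net_from_edges([("A", "B", 1.0), ("B", "C", 1.0)]))
        assert mt.table.loc["B", "betweenness"] == pytest.approx(1.0)
        assert mt.table.loc["B", "closeness"] == pytest.approx(0.5)
        assert mt.table.loc["A", "closeness"] == pytest.approx(1 / 3)
        assert mt.table.loc["B", "weighted_degree"] == pytest.approx(2.0)

    def test_star_eigenvector_ratio_is_sqrt3(self):
        # dominant eigenvector of K1,3: centre/leaf ratio = sqrt(3)
        mt = node_metrics(net_from_edges([("hub", leaf, 1.0) for leaf in "abc"]))
        assert mt.table.loc["hub", "eigenvector"] == pytest.approx(1.0)
        for leaf in "abc":
            assert 1.0 / mt.table.loc[leaf, "eigenvector"] == pytest.approx(np.sqrt(3), abs=1e-8)

    def test_complete_uniform_graph_has_equal_eigenvector(self):
        edges = [(a, b, 0.4) for a, b in itertools.combinations("ABCDE", 2)]
        mt = node_metrics(net_from_edges(edges))
        np.testing.assert_allclose(mt.table["eigenvector"], 1.0, atol=1e-8)

    def test_weighted_geodesics_use_inverse_weight(self):
        # A-B strong (0.5), B-C strong (0.5), A-C weak (0.1):
        # d(A,C) via B = 4 < direct 10, so B lies on the A-C geodesic
        mt = node_metrics(net_from_edges([("A", "B", 0.5), ("B", "C", 0.5), ("A", "C", 0.1)]))
        assert mt.table.loc["B", "betweenness"] == pytest.approx(1.0)
        assert mt.table.loc["A", "closeness"] == pytest.approx(1 / (2 + 4))

    def test_unit_weight_metrics_equal_unweighted_textbook_values(self):
        g = nx.petersen_graph()
        net = net_from_edges([(u, v, 1.0) for u, v in g.edges])
        mt = node_metrics(net)
        expected_btw = nx.betweenness_centrality(g, normalized=False)
        for v in g.nodes:
            assert mt.table.loc[v, "betweenness"] == pytest.approx(expected_btw[v])

    def test_eigenvector_satisfies_eigen_equation(self, sim_analysis):
        from socioscan.association import hwi, joint_counts
        from socioscan.scan_data import tally_sightings

        scans, _, roster = sim_analysis
        m = hwi(joint_counts(scans, "forest", "proximity", roster), tally_sightings(scans, "forest", roster))
        net = build_network(m)
        W = net.weight_matrix()
        x = eigenvector_centrality(W)
        lam = (x @ W @ x) / (x @ x)
        np.testing.assert_allclose(W @ x, lam * x, atol=1e-8 * max(1.0, lam))

    def test_eigenvector_agrees_with_networkx(self):
        rng = np.random.default_rng(3)
        W = rng.random((8, 8)) * (rng.random((8, 8)) < 0.6)
        W = (W + W.T) / 2
        np.fill_diagonal(W, 0)
        g = nx.from_numpy_array(W)
        ours = eigenvector_centrality(W)
        ref = nx.eigenvector_centrality_numpy(g, weight="weight")
        ref = np.array([ref[i] for i in range(8)])
        np.testing.assert_allclose(ours, ref / ref.max(), atol=1e-6)

    def test_empty_graph_warns_and_zeroes(self):
        g = nx.Graph()
        g.add_nodes_from("AB")
        with pytest.warns(UserWarning, match="no edges"):
            mt = node_metrics(SocialNetwork(g, "forest", "proximity"))
        assert (mt.table == 0).all().all()

    def test_degree_eigenvector_rank_correlation_on_dense_network(self, sim_analysis):
        # on a dense association network the two centralities should agree
        from socioscan.association import hwi, joint_counts
        from socioscan.scan_data import tally_sightings

        scans, _, roster = sim_analysis
        m = hwi(joint_counts(scans, "forest", "proximity", roster), tally_sightings(scans, "forest", roster))
        mt = node_metrics(build_network(m))
        rho = stats.spearmanr(mt.table["weighted_degree"], mt.table["eigenvector"]).statistic
        assert rho > 0.8


def best_two_partition_modularity(net):
    """Exhaustive modularity maximization over all 2-partitions (oracle)."""
    nodes = net.nodes
    best_q, best_parts = -1.0, None
    for bits in range(1, 2 ** (len(nodes) - 1)):
        membership = {v: (bits >> k) & 1 for k, v in enumerate(nodes)}
        q = modularity_of_partition(net, membership)
        if q > best_q:
            best_q, best_parts = q, membership
    return best_q, best_parts


class TestWalktrap:
    def two_cliques(self):
        edges = []
        for clique in ("ABCD", "EFGH"):
            edges += [(a, b, 1.0) for a, b in itertools.combinations(clique, 2)]
        edges.append(("D", "E", 0.1))
        return net_from_edges(edges)

    def test_recovers_two_cliques(self):
        net = self.two_cliques()
        membership, q = walktrap_clusters(net)
        groups = {}
        for v, c in membership.items():
            groups.setdefault(c, set()).add(v)
        assert sorted(map(frozenset, groups.values()), key=len) == [
            frozenset("ABCD"),
            frozenset("EFGH"),
        ] or set(map(frozenset, groups.values())) == {frozenset("ABCD"), frozenset("EFGH")}
        # and the found Q equals the exhaustive-2-partition optimum
        best_q, _ = best_two_partition_modularity(net)
        assert q == pytest.approx(best_q, abs=1e-12)

    def test_uniform_complete_graph_single_community(self):
        edges = [(a, b, 0.5) for a, b in itertools.combinations("ABCDEF", 2)]
        membership, q = walktrap_clusters(net_from_edges(edges))
        assert len(set(membership.values())) == 1
        assert q == pytest.approx(0.0, abs=1e-12)

    def test_edgeless_graph_gives_singletons(self):
        g = nx.Graph()
        g.add_nodes_from("ABC")
        membership, q = walktrap_clusters(SocialNetwork(g, "forest", "proximity"))
        assert sorted(membership.values()) == [0, 1, 2]
        assert q == 0.0

    def test_q_at_least_trivial_partition(self, sim_analysis):
        from socioscan.association import hwi, joint_counts
        from socioscan.scan_data import tally_sightings

        scans, _, roster = sim_analysis
        m = hwi(joint_counts(scans, "road", "proximity", roster), tally_sightings(scans, "road", roster))
        net = build_network(m)
        _, q = walktrap_clusters(net)
        trivial = modularity_of_partition(net, {v: 0 for v in net.nodes})
        assert q >= trivial - 1e-12

    def test_directed_network_clustered_on_summed_weights(self):
        hwi_mat = np.array([[0, 0.4, 0], [0.2, 0, 0], [0, 0, 0]])
        net = build_network(AssociationMatrix(["A", "B", "C"], "road", "affiliative", hwi_mat))
        membership, _ = walktrap_clusters(net)
        assert membership["A"] == membership["B"]
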