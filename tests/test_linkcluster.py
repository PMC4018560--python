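"""Link-community clustering: similarities, WPGMA, partition density, cut."""

import numpy as np
import pytest
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from hubdyn import (
    GroupGraph,
    LinkCommunities,
    build_similarity,
    cut_at_max_density,
    jaccard_similarity,
    mcquitty_cluster,
    partition_density,
    tanimoto_similarity,
    vertex_memberships,
)
from conftest import (
    brute_force_adjacent_pairs,
    direct_partition_density,
    exhaustive_best_cut_density,
    random_graph,
    wpgma_reference,
)


class TestJaccard:
    def test_single_common_neighbor(self, low_similarity_graph):
        # the only common neighbor of the non-shared endpoints is the keystone
        s = jaccard_similarity(low_similarity_graph, (0, 2), (1, 2))
        assert s == pytest.approx(1.0 / 3.0)

    def test_identical_neighborhoods(self, identical_neighborhood_graph):
        s = jaccard_similarity(identical_neighborhood_graph, (0, 2), (1, 2))
        assert s == 1.0

    def test_seven_vertex_enumeration(self):
        # i=0, j=1, k=2, plus leaves a..f=3..8: S = |{k}| / |{k,a,..,f}| = 1/7
        edges = [(0, 2), (1, 2), (0, 3), (0, 4), (0, 5), (1, 6), (1, 7), (1, 8)]
        g = GroupGraph(9, edges, [1.0] * 8)
        assert jaccard_similarity(g, (0, 2), (1, 2)) == pytest.approx(1.0 / 7.0)

    def test_rejects_disjoint_and_identical_edges(self, low_similarity_graph):
        with pytest.raises(ValueError):
            jaccard_similarity(low_similarity_graph, (0, 2), (0, 2))
        with pytest.raises(ValueError):
            jaccard_similarity(low_similarity_graph, (0, 3), (1, 4))


class TestTanimoto:
    def test_reduces_to_jaccard_on_unit_weights(self, low_similarity_graph):
        s = tanimoto_similarity(low_similarity_graph, (0, 2), (1, 2))
        assert s == pytest.approx(1.0 / 3.0)

    def test_identical_weight_vectors(self, identical_neighborhood_graph):
        g = GroupGraph(
            5,
            identical_neighborhood_graph.edges,
            [0.7, 0.7, 1.3, 1.3, 2.1, 2.1],
        )
        # w_0 and w_1 coincide over the union neighborhood -> S = 1
        assert tanimoto_similarity(g, (0, 2), (1, 2)) == pytest.approx(1.0)

    def test_hand_computed_vectors(self):
        # w_ik=2, w_ia=1, w_jk=2, w_jb=1 over {k,a,b}: dot=4, norms 5 and 5
        g = GroupGraph(5, [(0, 2), (1, 2), (0, 3), (1, 4)], [2.0, 2.0, 1.0, 1.0])
        assert tanimoto_similarity(g, (0, 2), (1, 2)) == pytest.approx(4.0 / 6.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_reduction_property_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        g = random_graph(rng, n_vertices=7, n_edges=10, weighted=False)
        for a, b in brute_force_adjacent_pairs(g):
            e1, e2 = map(tuple, (g.edges[a], g.edges[b]))
            assert tanimoto_similarity(g, e1, e2) == pytest.approx(
                jaccard_similarity(g, e1, e2), abs=1e-12
            )


class TestBuildSimilarity:
    def test_star_graph_pair_count(self):
        g = GroupGraph(4, [(0, 1), (0, 2), (0, 3)], [1.0] * 3)
        assert len(build_similarity(g, "jaccard")) == 3

    def test_path_graph_adjacency_requirement(self):
        g = GroupGraph(4, [(0, 1), (1, 2), (2, 3)], [1.0] * 3)
        pairs = {(a, b) for a, b, _ in build_similarity(g, "jaccard")}
        assert pairs == {(0, 1), (1, 2)}

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(100 + seed)
        g = random_graph(rng, n_vertices=7, n_edges=10)
        sims = build_similarity(g, "tanimoto")
        assert {(a, b) for a, b, _ in sims} == brute_force_adjacent_pairs(g)
        for a, b, s in sims:
            expected = tanimoto_similarity(
                g, tuple(g.edges[a]), tuple(g.edges[b])
            )
            assert s == pytest.approx(expected, abs=1e-12)

    def test_self_weight_variant_matches_scalar_form(self):
        rng = np.random.default_rng(5)
        g = random_graph(rng, n_vertices=6, n_edges=8)
        sims = build_similarity(g, "tanimoto", self_weight=True)
        for a, b, s in sims:
            expected = tanimoto_similarity(
                g, tuple(g.edges[a]), tuple(g.edges[b]), self_weight=True
            )
            assert s == pytest.approx(expected, abs=1e-12)


class TestMcQuitty:
    def test_identical_edges_merge_at_zero(self):
        z = mcquitty_cluster([(0, 1, 1.0)], 2)
        assert z[0, 2] == pytest.approx(0.0)

    def test_hand_executed_wpgma(self):
        # pairwise S = (0.8, 0.5, 0.5): first merge at d=0.2, then (0.5+0.5)/2
        sims = [(0, 1, 0.8), (0, 2, 0.5), (1, 2, 0.5)]
        z = mcquitty_cluster(sims, 3)
        assert z[0, 2] == pytest.approx(0.2)
        assert z[1, 2] == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_textbook_wpgma(self, seed):
        rng = np.random.default_rng(200 + seed)
        n = 9
        condensed = rng.uniform(0.05, 1.0, n * (n - 1) // 2)
        dense = squareform(condensed)
        heights = sorted(linkage(condensed, method="weighted")[:, 2])
        expected = wpgma_reference(dense)
        np.testing.assert_allclose(heights, expected, atol=1e-12)

    def test_single_edge_warns(self):
        with pytest.warns(UserWarning):
            z = mcquitty_cluster([], 1)
        assert z.shape == (0, 4)


class TestPartitionDensity:
    def test_triangle_is_clique_maximum(self):
        edges = np.array([[0, 1], [0, 2], [1, 2]])
        d, dc = partition_density(np.zeros(3, int), edges)
        assert d == pytest.approx(1.0)
        assert dc[0] == pytest.approx(1.0)

    def test_tree_is_minimum(self):
        edges = np.array([[0, 1], [1, 2], [2, 3]])
        d, dc = partition_density(np.zeros(3, int), edges)
        assert d == 0.0 and dc[0] == 0.0

    def test_triangle_plus_path_hand_value(self):
        # triangle (m=3, n=3) and 2-edge path (m=2, n=3): D = (2/5)*3*1/2 = 3/5
        edges = np.array([[0, 1], [0, 2], [1, 2], [3, 4], [4, 5]])
        labels = np.array([0, 0, 0, 1, 1])
        d, dc = partition_density(labels, edges)
        assert d == pytest.approx(0.6)
        assert dc == {0: pytest.approx(1.0), 1: 0.0}

    def test_single_edge_cluster_contributes_zero(self):
        edges = np.array([[0, 1], [2, 3]])
        d, dc = partition_density(np.array([0, 1]), edges)
        assert d == 0.0 and dc == {0: 0.0, 1: 0.0}

    def test_complete_graph_all_in_one_is_one(self):
        iu, ju = np.triu_indices(5, k=1)
        edges = np.column_stack([iu, ju])
        d, _ = partition_density(np.zeros(len(edges), int), edges)
        assert d == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_direct_formula(self, seed):
        rng = np.random.default_rng(300 + seed)
        g = random_graph(rng, n_vertices=8, n_edges=12)
        labels = rng.integers(0, 4, size=12)
        d, _ = partition_density(labels, g.edges)
        assert d == pytest.approx(
            direct_partition_density(labels, g.edges), abs=1e-12
        )


class TestMaxDensityCut:
    def test_two_disjoint_triangles(self):
        g = GroupGraph(
            6, [(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5)], [1.0] * 6
        )
        part = cut_at_max_density(
            mcquitty_cluster(build_similarity(g, "jaccard"), 6), g
        )
        assert part.n_clusters == 2
        assert part.density == pytest.approx(1.0)
        labels = part.labels
        assert len(set(labels[:3])) == 1 and len(set(labels[3:])) == 1
        assert labels[0] != labels[3]

    def test_single_triangle(self):
        g = GroupGraph(3, [(0, 1), (0, 2), (1, 2)], [1.0] * 3)
        part = cut_at_max_density(
            mcquitty_cluster(build_similarity(g, "jaccard"), 3), g
        )
        assert part.n_clusters == 1 and part.density == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(15))
    def test_attains_exhaustive_maximum(self, seed):
        rng = np.random.default_rng(400 + seed)
        g = random_graph(rng, n_vertices=7, n_edges=8)
        dendro = mcquitty_cluster(build_similarity(g, "tanimoto"), 8)
        part = cut_at_max_density(dendro, g)
        assert part.density == pytest.approx(
            exhaustive_best_cut_density(dendro, g.edges), abs=1e-12
        )

    def test_invariant_to_edge_input_order(self):
        rng = np.random.default_rng(9)
        g = random_graph(rng, n_vertices=8, n_edges=14)
        perm = rng.permutation(14)
        g2 = GroupGraph(8, g.edges[perm], g.weights[perm])
        # GroupGraph stores edges as given; cluster both and compare the
        # partition of the same physical edges
        def edge_partition(graph):
            dendro = mcquitty_cluster(
                build_similarity(graph, "tanimoto"), graph.n_edges
            )
            part = cut_at_max_density(dendro, graph)
            groups = {}
            for e, lab in zip(map(tuple, graph.edges), part.labels):
                groups.setdefault(lab, set()).add(e)
            return {frozenset(v) for v in groups.values()}

        assert edge_partition(g) == edge_partition(g2)


class TestVertexMemberships:
    def _membership(self, counts_per_cluster):
        """Build a toy star at vertex 0 with given per-cluster edge counts."""
        edges, labels = [], []
        nxt = 1
        for lab, cnt in enumerate(counts_per_cluster):
            for _ in range(cnt):
                edges.append((0, nxt))
                labels.append(lab)
                nxt += 1
        g = GroupGraph(nxt, edges, [1.0] * len(edges))
        from hubdyn.linkcluster import _make_partition

        part = _make_partition(np.array(labels), g.edges)
        return vertex_memberships(part, g).table.set_index("vertex").loc[0]

    def test_two_solid_networks_eligible(self):
        row = self._membership([3, 2])
        assert row["eligible"] and row["n_networks"] == 2
        assert row["second_largest"] == 2

    def test_thin_second_network_not_eligible(self):
        row = self._membership([5, 1])
        assert not row["eligible"] and row["second_largest"] == 1

    def test_single_network_not_eligible(self):
        row = self._membership([6])
        assert not row["eligible"] and row["n_networks"] == 1


class TestLinkCommunitiesEstimator:
    def test_fit_on_adjacency_matches_graph_fit(self):
        rng = np.random.default_rng(17)
        g = random_graph(rng, n_vertices=8, n_edges=12)
        est_graph = LinkCommunities(method="jaccard").fit(g)
        est_adj = LinkCommunities(method="jaccard").fit(g.adjacency())
        np.testing.assert_array_equal(est_graph.labels_, est_adj.labels_)
        assert est_graph.partition_density_ == est_adj.partition_density_

    def test_sklearn_contract(self):
        from sklearn.base import clone

        est = LinkCommunities(method="jaccard", min_second=3)
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()
        est.set_params(method="tanimoto")
        assert est.get_params()["method"] == "tanimoto"

    def test_fit_predict_returns_edge_labels(self):
        g = GroupGraph(
            6, [(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5)], [1.0] * 6
        )
        labels = LinkCommunities(method="jaccard").fit_predict(g)
        assert labels.shape == (6,)

    def test_rejects_asymmetric_input(self):
        with pytest.raises(ValueError):
            LinkCommunities().fit(np.array([[0.0, 1.0], [0.5, 0.0]]))
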