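import numpy as np
import pytest

import oracles
from micronets import (centralities, cluster_nodes, detect_hubs,
                       global_metrics)
from micronets.netanalysis import NodeCentralities, _modularity
from tests_helper import bundle_from_sim, bundle_unweighted


def ring(n):
    e = np.zeros((n, n), dtype=bool)
    for i in range(n):
        e[i, (i + 1) % n] = e[(i + 1) % n, i] = True
    return e


def star(n):
    e = np.zeros((n, n), dtype=bool)
    e[0, 1:] = e[1:, 0] = True
    return e


class TestCentralities:
    def test_star_center_degree(self):
        c = centralities(bundle_unweighted(star(5)))
        assert c.degree_norm[0] == pytest.approx(1.0)
        assert np.all(c.degree_norm[1:] == pytest.approx(0.25))

    def test_path_hand_values(self):
        # a-b-c with unit weights: betw*(b) = 1, closeness(b) = 0.5
        e = np.zeros((3, 3), dtype=bool)
        e[0, 1] = e[1, 0] = e[1, 2] = e[2, 1] = True
        c = centralities(bundle_unweighted(e))
        assert c.betweenness[1] == pytest.approx(1.0)
        assert c.betweenness_norm[1] == pytest.approx(1.0)
        assert c.closeness[1] == pytest.approx(0.5)
        assert c.closeness_norm[1] == pytest.approx(0.25)

    def test_eigenvector_max_is_one(self, random_weighted_bundle):
        b = random_weighted_bundle(8, 0.5, seed=0)
        c = centralities(b)
        assert c.eigenvector_norm.max() == pytest.approx(1.0)

    def test_eigenvector_matches_eigendecomposition(self,
                                                    random_weighted_bundle):
        for seed in range(5):
            b = random_weighted_bundle(7, 0.45, seed=seed)
            c = centralities(b)
            expect = oracles.eigenvector_centrality(b.similarity)
            if expect.max() > 0:
                expect = expect / expect.max()
            np.testing.assert_allclose(c.eigenvector_norm, expect,
                                       atol=1e-7)

    def test_weighted_against_bruteforce(self, random_weighted_bundle):
        for seed in range(6):
            b = random_weighted_bundle(7, 0.4, seed=10 + seed)
            c = centralities(b)
            np.testing.assert_allclose(
                c.betweenness, oracles.betweenness(b.edge_indicator,
                                                   b.dissimilarity),
                atol=1e-9)
            np.testing.assert_allclose(
                c.closeness, oracles.closeness(b.edge_indicator,
                                               b.dissimilarity),
                atol=1e-9)

    def test_unit_weights_equal_unweighted_textbook(self):
        # weighted implementation on 0/1 weights = unweighted values
        rng = np.random.default_rng(5)
        for seed in range(8):
            n = 6
            e = np.triu(rng.random((n, n)) < 0.5, 1)
            e = e | e.T
            b = bundle_unweighted(e)
            c = centralities(b)
            np.testing.assert_allclose(
                c.betweenness,
                oracles.betweenness(e, np.ones((n, n))), atol=1e-9)
            np.testing.assert_allclose(
                c.closeness, oracles.closeness(e, np.ones((n, n))),
                atol=1e-9)

    def test_empty_network_warns_all_zero(self):
        with pytest.warns(RuntimeWarning, match="empty"):
            c = centralities(bundle_unweighted(np.zeros((4, 4), dtype=bool)))
        assert np.all(c.degree == 0)

    def test_relabeling_invariance(self, random_weighted_bundle):
        b = random_weighted_bundle(7, 0.5, seed=21)
        perm = np.random.default_rng(0).permutation(7)
        sim = b.similarity[np.ix_(perm, perm)]
        b2 = bundle_from_sim(sim)
        c1 = centralities(b)
        c2 = centralities(b2)
        np.testing.assert_allclose(c2.degree, c1.degree[perm], atol=1e-12)
        np.testing.assert_allclose(c2.betweenness, c1.betweenness[perm],
                                   atol=1e-9)


class TestHubs:
    def make_cent(self, eig):
        eig = np.asarray(eig, dtype=float)
        n = len(eig)
        z = np.zeros(n)
        return NodeCentralities([f"n{i}" for i in range(n)], z, z, z, eig,
                                z, z, z, eig / eig.max(), True)

    def test_clear_outlier_is_hub(self):
        vals = np.concatenate([[1.0], np.random.default_rng(0).uniform(
            0.05, 0.5, 99)])
        c = self.make_cent(vals)
        assert "n0" in detect_hubs(c, ("eigenvector",),
                                   "empirical_quantile", 0.95)

    def test_intersection_rule_disjoint_sets_empty(self):
        n = 10
        deg = np.arange(1.0, 11.0)
        betw = np.arange(10.0, 0.0, -1.0)
        z = np.zeros(n)
        c = NodeCentralities([f"n{i}" for i in range(n)], deg, betw, z, z,
                             deg / 9, betw / 90, z, z, True)
        hubs = detect_hubs(c, ("degree", "betweenness"),
                           "empirical_quantile", 0.8)
        assert hubs == []

    def test_all_equal_warns_empty(self):
        c = self.make_cent(np.full(6, 2.0))
        with pytest.warns(RuntimeWarning):
            assert detect_hubs(c, ("eigenvector",)) == []

    def test_lognormal_quantile_calibrated(self):
        # hub fraction ~ (1 - q) when centralities are log-normal
        rng = np.random.default_rng(1)
        fractions = []
        for _ in range(500):
            vals = rng.lognormal(-1.0, 0.5, 60)
            c = self.make_cent(vals)
            hubs = detect_hubs(c, ("eigenvector",), "lognormal_quantile",
                               0.95)
            fractions.append(len(hubs) / 60)
        mean_frac = np.mean(fractions)
        se = np.sqrt(0.05 * 0.95 / (500 * 60))
        assert abs(mean_frac - 0.05) <= 3 * se + 0.01


class TestClustering:
    def two_cliques(self):
        sim = np.zeros((8, 8))
        for grp in (range(4), range(4, 8)):
            for i in grp:
                for j in grp:
                    if i != j:
                        sim[i, j] = 0.9
        return bundle_from_sim(sim)

    @pytest.mark.parametrize("method,params", [
        ("greedy_modularity", {}),
        ("hierarchical", {"k": 2}),
        ("edge_betweenness", {}),
    ])
    def test_two_cliques_recovered(self, method, params):
        b = self.two_cliques()
        out = cluster_nodes(b, method, **params)
        labs = out.labels
        assert len(set(labs[:4])) == 1
        assert len(set(labs[4:])) == 1
        assert labs[0] != labs[4]

    def test_hierarchical_k_equals_p(self, random_weighted_bundle):
        b = random_weighted_bundle(6, 0.8, seed=2)
        out = cluster_nodes(b, "hierarchical", k=6)
        assert len(set(out.labels)) == 6

    def test_unknown_linkage_errors(self, random_weighted_bundle):
        with pytest.raises(ValueError, match="linkage"):
            cluster_nodes(random_weighted_bundle(5, 0.9, seed=1),
                          "hierarchical", k=2, linkage="median")

    def test_isolated_nodes_labeled_zero(self):
        e = np.zeros((5, 5), dtype=bool)
        e[0, 1] = e[1, 0] = e[1, 2] = e[2, 1] = True
        out = cluster_nodes(bundle_unweighted(e), "greedy_modularity")
        assert out.labels[3] == out.labels[4] == 0
        assert np.all(out.labels[:3] > 0)

    def test_greedy_matches_bruteforce_on_barbell(self):
        e = np.zeros((6, 6), dtype=bool)
        for grp in (range(3), range(3, 6)):
            for i in grp:
                for j in grp:
                    if i != j:
                        e[i, j] = True
        e[2, 3] = e[3, 2] = True
        b = bundle_unweighted(e)
        out = cluster_nodes(b, "greedy_modularity")
        q_greedy = _modularity(b.similarity, out.labels)
        q_best, _ = oracles.best_modularity_partition(
            b.similarity)
        assert q_greedy == pytest.approx(q_best, abs=1e-12)


class TestGlobalMetrics:
    def test_triangle(self):
        e = np.ones((3, 3), dtype=bool)
        b = bundle_unweighted(e)
        g = global_metrics(b)
        assert g.avg_path_length == pytest.approx(1.0)
        assert g.clustering_coefficient == pytest.approx(1.0)
        assert g.density == pytest.approx(1.0)
        assert "fully_connected" in g.notes

    def test_star_clustering_zero(self):
        g = global_metrics(bundle_unweighted(star(5)))
        assert g.clustering_coefficient == 0.0

    def test_random_graph_against_bruteforce(self, random_weighted_bundle):
        for seed in range(5):
            b = random_weighted_bundle(7, 0.45, seed=30 + seed)
            clusters = cluster_nodes(b, "greedy_modularity")
            g = global_metrics(b, clusters)
            e, d, s = b.edge_indicator, b.dissimilarity, b.similarity
            assert g.avg_path_length == pytest.approx(
                oracles.avg_path_length(e, d), abs=1e-9)
            assert g.clustering_coefficient == pytest.approx(
                oracles.barrat_coefficient(e, s), abs=1e-9)
            assert g.modularity == pytest.approx(
                oracles.modularity(s, clusters.labels), abs=1e-9)
            assert g.vertex_connectivity == oracles.vertex_connectivity(e)
            assert g.edge_connectivity == oracles.edge_connectivity(e)
            assert g.density == pytest.approx(oracles.density(e))

    def test_all_in_one_partition_zero_modularity(self,
                                                  random_weighted_bundle):
        b = random_weighted_bundle(6, 0.5, seed=4)
        assert _modularity(b.similarity, np.ones(6, dtype=int)) == \
            pytest.approx(0.0, abs=1e-12)

    def test_adding_edge_never_decreases_density_or_degree(
            self, random_weighted_bundle):
        b = random_weighted_bundle(6, 0.4, seed=9)
        g1 = global_metrics(b)
        c1 = centralities(b, weighted=False)
        sim = b.similarity.copy()
        empty = np.argwhere(np.triu(~b.edge_indicator, 1))
        i, j = empty[0]
        sim[i, j] = sim[j, i] = 0.5
        b2 = bundle_from_sim(sim)
        g2 = global_metrics(b2)
        c2 = centralities(b2, weighted=False)
        assert g2.density >= g1.density
        assert c2.degree[i] >= c1.degree[i]
        assert c2.degree[j] >= c1.degree[j]
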