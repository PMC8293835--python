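import numpy as np
import pytest

from micronets import (CountMatrix, NbhdConfig, NormalizedMatrix, SparCC,
                       SparccConfig, clr_transform, correlate,
                       neighborhood_select, proportionality_rho, sparcc)
from micronets.estimators import _solve_basis


def norm_from(values):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    return NormalizedMatrix(values, [f"S{i}" for i in range(n)],
                            [f"T{i}" for i in range(p)], scale="counts")


def counts_from(values):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    return CountMatrix(values, [f"S{i}" for i in range(n)],
                       [f"T{i}" for i in range(p)])


class TestCorrelate:
    def test_perfect_linear_pearson(self):
        x = np.arange(1.0, 9.0)
        m = norm_from(np.column_stack([x, 2 * x + 1, 10 - x]))
        r = correlate(m, "pearson")
        assert r.values[0, 1] == pytest.approx(1.0)
        assert r.values[0, 2] == pytest.approx(-1.0)

    def test_monotone_transform_spearman(self):
        x = np.arange(1.0, 11.0)
        m = norm_from(np.column_stack([x, np.exp(x / 3), x]))
        r = correlate(m, "spearman")
        assert r.values[0, 1] == pytest.approx(1.0)

    def test_bicor_more_robust_than_pearson(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=40)
        y = 2 * x + rng.normal(scale=0.1, size=40)
        x_out = x.copy()
        x_out[0] = 40.0  # gross outlier
        m = NormalizedMatrix(np.column_stack([x_out, y]),
                             [f"S{i}" for i in range(40)], ["a", "b"],
                             scale="counts")
        bic = correlate(m, "bicor").values[0, 1]
        pea = correlate(m, "pearson").values[0, 1]
        assert abs(bic) > abs(pea)

    def test_constant_column_warns_and_zeroes(self):
        m = NormalizedMatrix(np.column_stack([np.arange(5.0),
                                              np.full(5, 2.0)]),
                             [f"S{i}" for i in range(5)], ["a", "b"],
                             scale="counts")
        with pytest.warns(RuntimeWarning, match="constant"):
            r = correlate(m, "pearson")
        assert r.values[0, 1] == 0.0

    def test_too_few_samples_errors(self):
        with pytest.raises(ValueError, match="3"):
            correlate(norm_from([[1, 2], [2, 1]]), "pearson")

    @pytest.mark.parametrize("method", ["pearson", "spearman", "bicor"])
    def test_symmetry_unit_diag_range(self, method, positive_counts):
        m = norm_from(positive_counts.values)
        r = correlate(m, method)
        np.testing.assert_allclose(r.values, r.values.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(r.values), 1.0)
        assert np.all(np.abs(r.values) <= 1 + 1e-12)


class TestSparcc:
    def test_basis_recovery_from_constructed_t(self):
        # forward-construct t from chosen basis variances with zero
        # correlation: t_ij = w_i + w_j; the solver must recover w
        rng = np.random.default_rng(4)
        w = rng.uniform(0.5, 3.0, 10)
        t = w[:, None] + w[None, :]
        np.fill_diagonal(t, 0.0)
        included = ~np.eye(10, dtype=bool)
        np.testing.assert_allclose(_solve_basis(t, included), w, atol=1e-9)

    def test_symmetric_unit_diagonal(self, positive_counts):
        r = sparcc(positive_counts, SparccConfig(n_outer=3, seed=0))
        np.testing.assert_allclose(r.values, r.values.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(r.values), 1.0)

    def test_reproducible_with_seed(self, positive_counts):
        cfg = SparccConfig(n_outer=1, seed=123)
        r1 = sparcc(positive_counts, cfg)
        r2 = sparcc(positive_counts, cfg)
        np.testing.assert_array_equal(r1.values, r2.values)

    def test_needs_four_taxa(self):
        with pytest.raises(ValueError, match="4"):
            sparcc(counts_from(np.ones((5, 3))))

    def test_independent_taxa_near_zero(self):
        # independent log-normal basis: off-diagonal correlations small
        rng = np.random.default_rng(9)
        latent = rng.normal(0, 1, size=(800, 12))
        comp = np.exp(latent)
        comp /= comp.sum(axis=1, keepdims=True)
        counts = np.vstack([rng.multinomial(5000, c) for c in comp])
        r = sparcc(counts_from(counts), SparccConfig(n_outer=5, seed=1))
        off = np.abs(r.values[~np.eye(12, dtype=bool)])
        assert off.mean() < 0.1


class TestProportionalityRho:
    def test_perfect_proportionality(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(1, 10, 30)
        m = counts_from(np.column_stack([x, 3.0 * x, rng.uniform(1, 10, 30)]))
        r = proportionality_rho(m)
        assert r.values[0, 1] == pytest.approx(1.0)
        np.testing.assert_allclose(r.values, r.values.T, atol=1e-12)

    def test_independent_columns_small_rho(self):
        # p large enough that the clr closure bias (~1/p) is small
        rng = np.random.default_rng(8)
        m = counts_from(np.exp(rng.normal(size=(2000, 25))))
        r = proportionality_rho(m)
        off = np.abs(r.values[~np.eye(25, dtype=bool)])
        assert off.mean() < 0.1
        assert np.all(off < 0.2)

    def test_rho_at_most_one(self, positive_counts):
        r = proportionality_rho(positive_counts)
        assert np.all(r.values <= 1 + 1e-12)

    def test_rejects_zeros(self, small_counts):
        with pytest.raises(ValueError, match="positive"):
            proportionality_rho(small_counts)


class TestNeighborhoodSelect:
    @staticmethod
    def chain_clr(p, n, seed, strength=0.3):
        rng = np.random.default_rng(seed)
        B = np.zeros((p, p))
        for i in range(p - 1):
            B[i, i + 1] = B[i + 1, i] = strength * rng.choice([-1, 1])
        lam = np.linalg.eigvalsh(B)[0]
        omega = B + (max(0.0, -lam) + 0.1) * np.eye(p)
        Z = rng.multivariate_normal(np.zeros(p), np.linalg.inv(omega),
                                    size=n)
        Z = Z - Z.mean(axis=1, keepdims=True)
        m = NormalizedMatrix(Z, [f"S{i}" for i in range(n)],
                             [f"T{i}" for i in range(p)], scale="clr-log")
        return m, np.abs(B) > 0

    def test_chain_recovery_f1(self):
        m, true = self.chain_clr(15, 500, seed=1)
        r = neighborhood_select(m, NbhdConfig(seed=1))
        est = r.values != 0
        np.fill_diagonal(est, False)
        tp = (est & true).sum() / 2
        fp = (est & ~true).sum() / 2
        fn = (~est & true).sum() / 2
        prec = tp / max(tp + fp, 1)
        rec = tp / max(tp + fn, 1)
        f1 = 2 * prec * rec / max(prec + rec, 1e-9)
        assert f1 >= 0.7

    def test_independent_few_false_edges(self):
        rng = np.random.default_rng(3)
        Z = rng.standard_normal((500, 15))
        Z -= Z.mean(axis=1, keepdims=True)
        m = NormalizedMatrix(Z, [f"S{i}" for i in range(500)],
                             [f"T{i}" for i in range(15)], scale="clr-log")
        r = neighborhood_select(m, NbhdConfig(seed=3))
        est = r.values != 0
        np.fill_diagonal(est, False)
        assert est.sum() / 2 <= 2

    @pytest.mark.parametrize("rule", ["and", "or"])
    def test_symmetric_output(self, rule):
        m, _ = self.chain_clr(8, 120, seed=5)
        r = neighborhood_select(m, NbhdConfig(symmetrize_rule=rule, seed=5))
        np.testing.assert_allclose(r.values, r.values.T, atol=1e-12)

    def test_requires_clr_scale(self, positive_counts):
        m = NormalizedMatrix(
            positive_counts.values /
            positive_counts.values.sum(1, keepdims=True),
            positive_counts.sample_ids, positive_counts.taxon_ids,
            scale="simplex")
        with pytest.raises(ValueError, match="clr"):
            neighborhood_select(m)

    def test_empty_lambda_grid_errors(self):
        with pytest.raises(ValueError, match="empty"):
            NbhdConfig(lambda_grid=[])


class TestInvariances:
    def test_taxon_permutation_invariance(self, positive_counts):
        perm = np.array([3, 1, 5, 0, 2, 4])
        permuted = CountMatrix(positive_counts.values[:, perm],
                               positive_counts.sample_ids,
                               [positive_counts.taxon_ids[i] for i in perm])
        m1 = norm_from(positive_counts.values)
        m2 = norm_from(permuted.values)
        r1 = correlate(m1, "pearson").values
        r2 = correlate(m2, "pearson").values
        np.testing.assert_allclose(r2, r1[np.ix_(perm, perm)], atol=1e-12)
        rho1 = proportionality_rho(positive_counts).values
        rho2 = proportionality_rho(permuted).values
        np.testing.assert_allclose(rho2, rho1[np.ix_(perm, perm)],
                                   atol=1e-12)

    def test_pearson_on_clr_scale_invariant(self, positive_counts):
        rng = np.random.default_rng(0)
        scaled = positive_counts.values * rng.uniform(1, 50, (10, 1))
        g1 = clr_transform(positive_counts.values)
        g2 = clr_transform(scaled)
        m1 = NormalizedMatrix(g1, positive_counts.sample_ids,
                              positive_counts.taxon_ids, scale="clr-log")
        m2 = NormalizedMatrix(g2, positive_counts.sample_ids,
                              positive_counts.taxon_ids, scale="clr-log")
        np.testing.assert_allclose(correlate(m1, "pearson").values,
                                   correlate(m2, "pearson").values,
                                   atol=1e-12)


def test_sklearn_estimator_contract(positive_counts):
    from sklearn.base import clone

    est = SparCC(n_outer=2, random_state=0)
    params = est.get_params()
    assert params["n_outer"] == 2
    cloned = clone(est)
    r1 = est.fit(positive_counts.values).correlation_
    r2 = cloned.fit(positive_counts.values).correlation_
    np.testing.assert_array_equal(r1, r2)
    est.set_params(n_outer=1)
    assert est.get_params()["n_outer"] == 1
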