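"""Regression layer: VCV construction, GLS/PGLS, quasi-Poisson, effects."""

import math

import dendropy
import numpy as np
import pytest

from epirange.phylo_regression import (
    Z95,
    aggregate_trees,
    effect_size_percent,
    gls_fit,
    lambda_transform,
    ols_log,
    pgls_ml,
    phylo_vcv,
    quasipoisson_glm,
)
from epirange.synthetic_data import simulate_phylo_noise, simulate_tree


def newick(s):
    return dendropy.Tree.get(data=s, schema="newick")


class TestPhyloVcv:
    def test_three_taxon_tree(self):
        C = phylo_vcv(newick("((A:1,B:1):1,C:2);"), ["A", "B", "C"])
        assert np.allclose(C, [[2, 1, 0], [1, 2, 0], [0, 0, 2]])

    def test_star_tree_gives_identity(self):
        C = phylo_vcv(newick("(A:1,B:1,C:1,D:1);"), list("ABCD"))
        assert np.allclose(C, np.eye(4))

    def test_matches_pairwise_mrca_oracle_on_random_tree(self):
        tree = simulate_tree(50, 1.0, seed=11)
        taxa = sorted(l.taxon.label for l in tree.leaf_node_iter())
        C = phylo_vcv(tree, taxa)
        # independent oracle: MRCA depth via patristic distances,
        # depth(mrca) = (d_root_i + d_root_j - d_ij) / 2
        pdm = tree.phylogenetic_distance_matrix()
        tns = {t.label: t for t in tree.taxon_namespace}
        droot = {
            l.taxon.label: l.distance_from_root() for l in tree.leaf_node_iter()
        }
        for i, a in enumerate(taxa):
            assert C[i, i] == pytest.approx(droot[a], abs=1e-12)
            for j in range(i + 1, len(taxa)):
                b = taxa[j]
                dij = pdm.patristic_distance(tns[a], tns[b])
                assert C[i, j] == pytest.approx(
                    (droot[a] + droot[b] - dij) / 2.0, abs=1e-10
                )

    def test_extra_tips_ignored_missing_taxa_error(self):
        tree = newick("((A:1,B:1):1,C:2);")
        C = phylo_vcv(tree, ["A", "C"])
        assert np.allclose(C, [[2, 0], [0, 2]])
        with pytest.raises(ValueError, match="ZZ"):
            phylo_vcv(tree, ["A", "ZZ"])


class TestLambdaTransform:
    def test_scales_off_diagonal_only(self):
        C = np.array([[2.0, 1.0], [1.0, 2.0]])
        assert np.allclose(lambda_transform(C, 0.5), [[2, 0.5], [0.5, 2]])
        assert np.allclose(lambda_transform(C, 1.0), C)
        assert np.allclose(lambda_transform(C, 0.0), np.diag([2.0, 2.0]))

    def test_out_of_range_lambda_error(self):
        with pytest.raises(ValueError):
            lambda_transform(np.eye(2), 1.5)


class TestGls:
    def test_identity_covariance_reduces_to_ols(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([np.ones(30), rng.normal(size=30)])
        y = X @ [1.0, 0.5] + rng.normal(size=30)
        g = gls_fit(y, X, np.eye(30))
        beta_ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.allclose(g.beta, beta_ols, atol=1e-12)

    def test_three_observation_intercept_only_oracle(self):
        V = np.array([[2.0, 1.0, 0.0], [1.0, 2.0, 0.0], [0.0, 0.0, 2.0]])
        y = np.array([1.0, 2.0, 3.0])
        X = np.ones((3, 1))
        fit = gls_fit(y, X, V)
        Vi = np.linalg.inv(V)
        oracle = (X.T @ Vi @ y) / (X.T @ Vi @ X)
        assert fit.beta[0] == pytest.approx(oracle.item(), abs=1e-10)

    def test_singular_covariance_and_rank_deficiency_errors(self):
        y = np.arange(4.0)
        X = np.ones((4, 1))
        with pytest.raises(ValueError, match="positive definite"):
            gls_fit(y, X, np.ones((4, 4)))
        X2 = np.column_stack([np.ones(4), np.ones(4)])
        with pytest.raises(ValueError, match="rank"):
            gls_fit(y, X2, np.eye(4))

    def test_taxon_permutation_leaves_fit_invariant(self):
        tree = simulate_tree(20, 1.0, seed=3)
        taxa = sorted(l.taxon.label for l in tree.leaf_node_iter())
        rng = np.random.default_rng(5)
        X = np.column_stack([np.ones(20), rng.integers(0, 2, 20).astype(float)])
        y = rng.normal(size=20)
        V = lambda_transform(phylo_vcv(tree, taxa), 0.7)
        base = gls_fit(y, X, V)
        perm = rng.permutation(20)
        permuted = gls_fit(y[perm], X[perm], V[np.ix_(perm, perm)])
        assert np.allclose(base.beta, permuted.beta, atol=1e-10)
        assert base.loglik == pytest.approx(permuted.loglik, abs=1e-8)


class TestPgls:
    def test_profile_optimum_beats_grid(self):
        tree = simulate_tree(40, 1.0, seed=9)
        taxa, eps = simulate_phylo_noise(tree, 0.6, 0.3, seed=10)
        rng = np.random.default_rng(11)
        X = np.column_stack([np.ones(40), rng.integers(0, 2, 40).astype(float)])
        y = 1.0 + 0.3 * X[:, 1] + eps
        fit = pgls_ml(y, X, tree, taxa)
        C = phylo_vcv(tree, taxa)
        for lam in np.linspace(0, 1, 101):
            grid_ll = gls_fit(y, X, lambda_transform(C, lam)).loglik
            assert fit.loglik >= grid_ll - 1e-6

    def test_fixed_lambda_zero_equals_log_ols_on_ultrametric_tree(self):
        tree = simulate_tree(30, 1.0, seed=21)
        taxa, eps = simulate_phylo_noise(tree, 0.5, 0.2, seed=22)
        rng = np.random.default_rng(23)
        X = np.column_stack([np.ones(30), rng.integers(0, 2, 30).astype(float)])
        y = 2.0 + 0.4 * X[:, 1] + eps
        p = pgls_ml(y, X, tree, taxa, lam=0.0)
        o = ols_log(np.exp(y), X)
        assert np.allclose(p.beta, o.beta, atol=1e-8)
        assert np.allclose(p.se, o.se, atol=1e-8)

    def test_lambda_discrimination_under_simulation(self):
        """Data generated with lambda 0 vs 1 push the estimate to the
        matching end of the interval in most replicates."""
        hits0 = hits1 = 0
        n_rep = 25
        for s in range(n_rep):
            tree = simulate_tree(150, 1.0, seed=1000 + s)
            X = np.ones((150, 1))
            taxa, e0 = simulate_phylo_noise(tree, 0.0, 0.3, seed=2000 + s)
            hits0 += pgls_ml(e0, X, tree, taxa).lambda_hat < 0.1
            taxa, e1 = simulate_phylo_noise(tree, 1.0, 1.0, seed=3000 + s)
            hits1 += pgls_ml(e1, X, tree, taxa).lambda_hat > 0.85
        assert hits0 >= 0.8 * n_rep
        assert hits1 >= 0.8 * n_rep

    def test_zero_length_tree_error(self):
        tree = newick("((A:0,B:0):0,C:0);")
        with pytest.raises(ValueError):
            pgls_ml(np.array([1.0, 2.0, 3.0]), np.ones((3, 1)), tree, ["A", "B", "C"])


class TestOlsLog:
    def test_binary_slope_is_log_ratio_of_geometric_means(self):
        y = np.array([2.0, 8.0, 3.0, 27.0])  # geo means 4 and 9
        X = np.array([[1, 0], [1, 0], [1, 1], [1, 1]], float)
        fit = ols_log(y, X)
        assert fit.beta[1] == pytest.approx(math.log(9.0 / 4.0), abs=1e-12)

    def test_exact_loglinear_data_recovered_with_zero_residual(self):
        rng = np.random.default_rng(2)
        X = np.column_stack([np.ones(10), rng.normal(size=10)])
        b = np.array([0.7, -0.4])
        fit = ols_log(np.exp(X @ b), X)
        assert np.allclose(fit.beta, b, atol=1e-12)
        assert np.allclose(fit.se, 0.0, atol=1e-7)

    def test_nonpositive_values_error_lists_offenders(self):
        with pytest.raises(ValueError, match=r"\[1\]"):
            ols_log([1.0, 0.0, 2.0], np.ones((3, 1)))

    def test_recovers_planted_effect_within_three_se(self):
        rng = np.random.default_rng(77)
        n = 500
        x = rng.integers(0, 2, n).astype(float)
        X = np.column_stack([np.ones(n), x])
        b1 = math.log(1.5)
        y = np.exp(1.0 + b1 * x + rng.normal(scale=0.8, size=n))
        fit = ols_log(y, X)
        assert abs(fit.beta[1] - b1) <= 3 * fit.se[1]


class TestQuasiPoisson:
    def test_two_group_closed_form(self):
        X = np.array([[1, 0], [1, 0], [1, 1], [1, 1]], float)
        fit = quasipoisson_glm([1, 3, 2, 6], X)
        assert fit.beta[1] == pytest.approx(math.log(2.0), abs=1e-8)
        assert fit.dispersion_phi == pytest.approx(1.5, abs=1e-8)

    def test_equal_counts_give_zero_slope_and_flagged_zero_dispersion(self):
        X = np.array([[1, 0], [1, 0], [1, 1], [1, 1]], float)
        with pytest.warns(RuntimeWarning, match="dispersion"):
            fit = quasipoisson_glm([4, 4, 4, 4], X)
        assert fit.beta[1] == pytest.approx(0.0, abs=1e-10)
        assert fit.dispersion_phi == 0.0

    def test_all_zero_group_with_own_indicator_errors(self):
        X = np.array([[1, 0], [1, 0], [1, 1], [1, 1]], float)
        with pytest.raises(ValueError, match="all-zero"):
            quasipoisson_glm([1, 2, 0, 0], X)

    def test_overdispersed_counts_recovered(self):
        rng = np.random.default_rng(123)
        n = 2000
        x = rng.uniform(-1, 1, n)
        X = np.column_stack([np.ones(n), x])
        mu = np.exp(1.0 + 0.5 * x)
        size = 2.0
        y = rng.negative_binomial(size, size / (size + mu))
        fit = quasipoisson_glm(y, X)
        assert fit.dispersion_phi > 1.0
        assert abs(fit.beta[1] - 0.5) <= 3 * fit.se[1]

    def test_matches_statsmodels_pearson_scaled_glm(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(8)
        n = 120
        x = rng.normal(size=n)
        X = np.column_stack([np.ones(n), x])
        y = rng.poisson(np.exp(0.5 + 0.3 * x))
        y[0] = max(y[0], 1)
        fit = quasipoisson_glm(y, X)
        ref = sm.GLM(y, X, family=sm.families.Poisson()).fit(scale="X2")
        assert np.allclose(fit.beta, ref.params, atol=1e-7)
        assert np.allclose(fit.se, ref.bse, atol=1e-7)
        assert fit.dispersion_phi == pytest.approx(ref.scale, rel=1e-8)


class TestEffectSize:
    def test_zero_coefficient_zero_percent(self):
        fit = _fit([0.0], [0.0])
        e = effect_size_percent(fit, 0)
        assert (e.percent, e.ci_low, e.ci_high) == (0.0, 0.0, 0.0)

    def test_stated_transform(self):
        e = effect_size_percent(_fit([0.25], [0.1]), 0)
        assert e.percent == pytest.approx(28.4, abs=0.05)
        assert e.ci_low == pytest.approx(5.5, abs=0.05)
        assert e.ci_high == pytest.approx(56.2, abs=0.05)

    def test_fewer_convention(self):
        e = effect_size_percent(_fit([math.log(0.42)], [0.01]), 0)
        assert e.percent == pytest.approx(-58.0, abs=1e-9)

    def test_index_out_of_range(self):
        with pytest.raises(ValueError):
            effect_size_percent(_fit([0.1], [0.1]), 3)


def _fit(beta, se):
    from epirange.phylo_regression import RegressionFit

    return RegressionFit(
        model="ols_log", beta=np.array(beta), se=np.array(se), n_obs=10,
        residual_df=9,
    )


class TestAggregateTrees:
    def test_two_fit_mean_and_spread(self):
        f1 = _fit([1.0, 0.2], [0.1, 0.1])
        f2 = _fit([1.0, 0.4], [0.1, 0.1])
        s = aggregate_trees([f1, f2])
        assert s.beta_mean[1] == pytest.approx(0.3)
        assert s.beta_spread[1] == pytest.approx(0.141421, abs=1e-6)

    def test_identical_fits_zero_spread(self):
        fits = [_fit([1.0, 0.2], [0.1, 0.1]) for _ in range(100)]
        s = aggregate_trees(fits)
        assert np.allclose(s.beta_spread, 0.0)
        assert s.n_trees == 100

    def test_heterogeneous_designs_error(self):
        with pytest.raises(ValueError, match="heterogeneous"):
            aggregate_trees([_fit([1.0], [0.1]), _fit([1.0, 0.2], [0.1, 0.1])])
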