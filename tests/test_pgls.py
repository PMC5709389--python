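"""GLS core, lambda profile likelihood, boundary LRTs."""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy.stats import multivariate_normal

from seasonbrain import (
    ModelSpec,
    PGLSRegression,
    fit_pgls,
    gls_fit,
    lambda_transform,
    lrt_lambda,
    profile_lambda,
    simulate_traits,
    simulate_yule_tree,
    vcv_matrix,
)
from seasonbrain.simulate import rescale_tree_height
from seasonbrain.tree import tip_labels


def _dataset(n, seed, k=1):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, k))
    y = rng.normal(size=n)
    return X, y


def _tree_V(n, seed):
    t = simulate_yule_tree(n, 1.0, seed=seed)
    rescale_tree_height(t)
    return t, vcv_matrix(t)


class TestGlsCore:
    def test_identity_covariance_equals_ols(self):
        """With V = I the GLS fit must reproduce OLS exactly."""
        X, y = _dataset(25, 0, k=2)
        est = PGLSRegression().fit(X, y)
        ols = sm.OLS(y, sm.add_constant(X)).fit()
        np.testing.assert_allclose(est.params_, ols.params, atol=1e-12)
        np.testing.assert_allclose(est.bse_, ols.bse, atol=1e-12)
        np.testing.assert_allclose(est.tvalues_, ols.tvalues, atol=1e-10)
        np.testing.assert_allclose(est.pvalues_, ols.pvalues, atol=1e-12)
        assert est.df_resid_ == ols.df_resid

    def test_perfect_linear_fit(self, caplog):
        X = np.linspace(0, 1, 10).reshape(-1, 1)
        y = 2.0 + 3.0 * X[:, 0]
        D = np.column_stack([np.ones(10), X])
        with caplog.at_level("WARNING", logger="seasonbrain.pgls"):
            beta, sigma2, loglik, resid = gls_fit(y, D, np.eye(10))
        np.testing.assert_allclose(beta, [2.0, 3.0], atol=1e-10)
        np.testing.assert_allclose(resid, 0.0, atol=1e-10)
        assert sigma2 == pytest.approx(0.0, abs=1e-12)
        assert np.isfinite(loglik)

    def test_covariance_scale_leaves_beta_unchanged(self):
        _, V = _tree_V(12, 3)
        rng = np.random.default_rng(4)
        D = np.column_stack([np.ones(12), rng.normal(size=12)])
        y = rng.normal(size=12)
        b1, *_ = gls_fit(y, D, V.matrix)
        b2, *_ = gls_fit(y, D, 7.3 * V.matrix)
        np.testing.assert_allclose(b1, b2, rtol=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_loglik_matches_mvn_density(self, seed):
        """Direct multivariate-normal evaluation as an independent oracle."""
        n = 4 + seed
        _, V = _tree_V(n, seed + 10)
        rng = np.random.default_rng(seed)
        D = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = rng.normal(size=n)
        beta, sigma2, loglik, _ = gls_fit(y, D, V.matrix)
        direct = multivariate_normal.logpdf(y, mean=D @ beta, cov=sigma2 * V.matrix)
        assert loglik == pytest.approx(direct, abs=1e-8)

    def test_collinear_design_rejected(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=20)
        X = np.column_stack([x, 2.0 * x])
        with pytest.raises(ValueError, match="collinear"):
            PGLSRegression().fit(X, rng.normal(size=20))

    def test_no_residual_df_rejected(self):
        X, y = _dataset(3, 6, k=3)
        with pytest.raises(ValueError, match="residual df"):
            PGLSRegression().fit(X, y)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            gls_fit(np.ones(5), np.ones((5, 2)), np.eye(4))


class TestProfileLambda:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_fine_grid_oracle(self, seed):
        tree, V = _tree_V(20, seed + 20)
        order = tip_labels(tree)
        rng = np.random.default_rng(seed)
        D = np.column_stack([np.ones(20), rng.normal(size=20)])
        y = simulate_traits(
            tree, D, [0.0, 0.3], lam=rng.uniform(0, 1), sigma2=0.05,
            seed=seed, species_order=order,
        )
        lam_hat = profile_lambda(y, D, V)
        grid = np.linspace(0, 1, 10001)
        lls = [gls_fit(y, D, lambda_transform(V, g).matrix)[2] for g in grid]
        assert abs(lam_hat - grid[int(np.argmax(lls))]) < 1e-3

    def test_recovers_no_signal(self):
        """iid traits on a deep tree: median lambda-hat near zero."""
        lams = []
        for rep in range(50):
            tree, V = _tree_V(100, 1000 + rep)
            rng = np.random.default_rng(rep)
            y = rng.normal(size=100)  # star-like, no tree structure
            D = np.ones((100, 1))
            lams.append(profile_lambda(y, D, V))
        assert np.median(lams) < 0.1

    def test_recovers_brownian_motion(self):
        """Pure Brownian traits: median lambda-hat near one."""
        lams = []
        for rep in range(50):
            tree, V = _tree_V(100, 2000 + rep)
            y = simulate_traits(
                tree, np.ones((100, 1)), [0.0], lam=1.0, sigma2=1.0, seed=rep
            )
            lams.append(profile_lambda(y, np.ones((100, 1)), V))
        assert np.median(lams) > 0.9


class TestLrtLambda:
    def test_zero_statistic_gives_p_one(self):
        assert lrt_lambda(-12.3, -12.3) == pytest.approx(1.0)

    def test_chi2_quantile(self):
        # 2 dlnL = 3.841 is the 5% critical value of chi-square(1)
        assert lrt_lambda(0.0, -3.841 / 2) == pytest.approx(0.05, abs=1e-3)

    def test_monotone_in_statistic(self):
        stats = np.linspace(0, 10, 25)
        ps = [lrt_lambda(s / 2, 0.0) for s in stats]
        assert np.all(np.diff(ps) <= 0)

    def test_negative_statistic_rejected(self):
        with pytest.raises(ValueError, match="negative LR"):
            lrt_lambda(0.0, 1.0)


class TestFitPgls:
    @pytest.fixture
    def fitted(self, analysis_inputs):
        import seasonbrain

        traits, climate, tree, daily = analysis_inputs
        table, tree = seasonbrain.build_analysis_table(traits, climate, tree)
        spec = ModelSpec(
            "brain_cv_temp", "log_brain", ["cv_temp"], ["log_svl", "log_mass"]
        )
        return table, tree, fit_pgls(table, spec, tree)

    def test_planted_negative_temperature_slope(self, fitted):
        """Bivariate brain ~ CV-temp model: negative slope, p < 0.05."""
        _, _, fit = fitted
        row = fit.term("cv_temp")
        assert row["beta"] < 0
        assert row["p"] < 0.05
        assert 0 <= fit.lambda_hat <= 1
        assert fit.n == 30 and fit.df_resid == 26

    def test_boundary_loglik_dominated(self, fitted):
        _, _, fit = fitted
        assert fit.p_lambda_vs_0 >= 0 and fit.p_lambda_vs_1 >= 0

    def test_refit_at_estimate_is_idempotent(self, fitted):
        table, tree, fit = fitted
        spec = ModelSpec(
            "brain_cv_temp", "log_brain", ["cv_temp"], ["log_svl", "log_mass"]
        )
        refit = fit_pgls(table, spec, tree, lam=fit.lambda_hat)
        np.testing.assert_allclose(refit.terms["beta"], fit.terms["beta"], rtol=1e-9)
        np.testing.assert_allclose(refit.terms["se"], fit.terms["se"], rtol=1e-9)
        np.testing.assert_allclose(refit.terms["t"], fit.terms["t"], rtol=1e-9)

    def test_species_missing_from_tree_rejected(self, fitted):
        table, tree, _ = fitted
        bad = table.rename(index={table.index[0]: "not_a_tip"})
        spec = ModelSpec("m", "log_brain", ["cv_temp"])
        with pytest.raises(KeyError, match="not_a_tip"):
            fit_pgls(bad, spec, tree)

    def test_missing_values_rejected(self, fitted):
        table, tree, _ = fitted
        bad = table.copy()
        bad.loc[bad.index[2], "cv_temp"] = np.nan
        spec = ModelSpec("m", "log_brain", ["cv_temp"])
        with pytest.raises(ValueError, match="missing"):
            fit_pgls(bad, spec, tree)
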