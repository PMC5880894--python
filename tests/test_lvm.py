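import numpy as np
import pytest
import statsmodels.api as sm

from cyanoniche.compositional import ClrMatrix, GRAIN_INTRA
from cyanoniche.datamodel import CountTable, DataError, EnvMatrix
from cyanoniche.lvm import (
    build_design,
    environmental_correlations,
    environmental_correlations_per_dimension,
    fit_lvm,
    fit_polynomial,
    prevalence_filter,
    residual_correlations,
    univariate_best_fit,
)


class TestBuildDesign:
    def test_standardization_and_squares(self):
        env = EnvMatrix(["a", "b", "c"], ["x"], np.array([[1.0], [2.0], [3.0]]))
        design = build_design(env, include_quadratic=True)
        np.testing.assert_allclose(design.values[:, 0], [-1, 0, 1])
        np.testing.assert_allclose(design.values[:, 1], [1, 0, 1])
        assert design.columns == ["x", "x^2"]

    def test_constant_covariate_errors(self):
        env = EnvMatrix(["a", "b"], ["flat"], np.array([[2.0], [2.0]]))
        with pytest.raises(DataError, match="flat"):
            build_design(env)

    def test_no_quadratic(self, env_two_samples):
        design = build_design(env_two_samples, include_quadratic=False)
        assert len(design.columns) == 6

    def test_missing_rows_dropped_listwise(self):
        values = np.array([[1.0, 2.0], [np.nan, 3.0], [2.0, 4.0], [3.0, 5.0]])
        env = EnvMatrix(list("abcd"), ["u", "v"], values)
        design = build_design(env, include_quadratic=False)
        assert design.sample_ids == ["a", "c", "d"]

    def test_linear_columns_standardized_property(self, rng):
        env = EnvMatrix(
            [f"s{i}" for i in range(30)],
            ["u", "v"],
            rng.standard_normal((30, 2)) * 5 + 3,
        )
        design = build_design(env)
        np.testing.assert_allclose(design.values[:, :2].mean(axis=0), 0, atol=1e-9)
        np.testing.assert_allclose(design.values[:, :2].std(axis=0, ddof=1), 1, atol=1e-9)
        np.testing.assert_allclose(design.values[:, 2:], design.values[:, :2] ** 2)


class TestPrevalenceFilter:
    def _fixture(self, present_a, present_b, n=135):
        counts = np.zeros((2, n), dtype=int)
        counts[0, :present_a] = 5
        counts[1, :present_b] = 5
        ct = CountTable(["a", "b"], [f"s{j}" for j in range(n)], counts)
        values = np.vstack([np.ones(n), -np.ones(n)])
        clr_m = ClrMatrix(["a", "b"], list(ct.sample_ids), values, GRAIN_INTRA)
        return ct, clr_m

    def test_boundary_kept(self):
        ct, clr_m = self._fixture(95, 135)  # 95/135 = 0.7037 >= 0.70
        out = prevalence_filter(clr_m, ct, 0.70)
        assert "a" in out.entity_ids

    def test_below_boundary_dropped(self):
        ct, clr_m = self._fixture(94, 135)  # 94/135 = 0.696
        out = prevalence_filter(clr_m, ct, 0.70)
        assert out.entity_ids == ["b"]

    def test_zero_threshold_identity(self):
        ct, clr_m = self._fixture(10, 20)
        out = prevalence_filter(clr_m, ct, 0.0)
        assert out.entity_ids == ["a", "b"]

    def test_nothing_survives_errors(self):
        ct, clr_m = self._fixture(5, 5)
        with pytest.raises(DataError):
            prevalence_filter(clr_m, ct, 0.9)


def simulate_lvm_data(n, d_taxa, p, n_latent, sigma, seed, latent_scale=0.5):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n, p))
    beta0 = rng.standard_normal(d_taxa)
    beta = rng.standard_normal((d_taxa, p))
    loadings = latent_scale * rng.standard_normal((d_taxa, n_latent))
    z = rng.standard_normal((n, n_latent))
    y = beta0 + x @ beta.T + z @ loadings.T + sigma * rng.standard_normal((n, d_taxa))
    return y, x, beta0, beta, loadings


class TestFitLvm:
    def test_d0_equals_ols_exactly(self):
        y, x, *_ = simulate_lvm_data(60, 5, 3, 0, 0.5, seed=1)
        fit = fit_lvm(y, x, n_latent=0)
        for j in range(5):
            ols = sm.OLS(y[:, j], sm.add_constant(x)).fit()
            np.testing.assert_allclose(fit.intercept[j], ols.params[0], atol=1e-8)
            np.testing.assert_allclose(fit.beta[j], ols.params[1:], atol=1e-8)

    def test_parameter_recovery(self):
        y, x, beta0, beta, _ = simulate_lvm_data(200, 10, 4, 2, 0.1, seed=7)
        fit = fit_lvm(y, x, n_latent=2, seed=0)
        rmse = np.sqrt(np.mean((fit.beta - beta) ** 2))
        assert rmse < 0.1
        assert fit.converged

    def test_duplicate_taxa_get_identical_beta(self):
        y, x, *_ = simulate_lvm_data(80, 3, 2, 0, 0.3, seed=2)
        y_dup = np.column_stack([y, y[:, 0]])
        fit = fit_lvm(y_dup, x, n_latent=2, seed=0)
        np.testing.assert_allclose(fit.beta[0], fit.beta[3], atol=1e-6)

    def test_deterministic_given_seed(self):
        y, x, *_ = simulate_lvm_data(100, 6, 3, 2, 0.2, seed=3)
        a = fit_lvm(y, x, n_latent=2, seed=5)
        b = fit_lvm(y, x, n_latent=2, seed=5)
        np.testing.assert_array_equal(a.beta, b.beta)
        np.testing.assert_array_equal(a.loadings, b.loadings)

    def test_loadings_identified_lower_triangular(self):
        y, x, *_ = simulate_lvm_data(150, 8, 3, 2, 0.2, seed=4)
        fit = fit_lvm(y, x, n_latent=2, seed=0)
        assert abs(fit.loadings[0, 1]) < 1e-8
        assert fit.loadings[0, 0] >= 0
        assert fit.loadings[1, 1] >= 0

    def test_too_few_samples_errors(self):
        with pytest.raises(DataError, match="too few samples"):
            fit_lvm(np.zeros((5, 3)), np.zeros((5, 4)), n_latent=2)


class TestEnvironmentalCorrelations:
    def test_identical_beta_corr_one(self):
        x = np.random.default_rng(0).standard_normal((50, 3))
        y = np.column_stack([x @ np.array([1.0, 2.0, -1.0])] * 2)
        fit = fit_lvm(y, x, n_latent=0)
        ec = environmental_correlations(fit, x)
        assert ec.corr[0, 1] == pytest.approx(1.0, abs=1e-8)

    def test_negated_beta_corr_minus_one(self):
        x = np.random.default_rng(0).standard_normal((50, 3))
        eta = x @ np.array([1.0, 2.0, -1.0])
        fit = fit_lvm(np.column_stack([eta, -eta]), x, n_latent=0)
        ec = environmental_correlations(fit, x)
        assert ec.corr[0, 1] == pytest.approx(-1.0, abs=1e-8)

    def test_kernel_correlation_recovered(self):
        # two taxa with correlated niche coefficients (r = 0.8)
        rng = np.random.default_rng(11)
        n, p = 200, 4
        x = rng.standard_normal((n, p))
        cov = np.array([[1.0, 0.8], [0.8, 1.0]])
        chol = np.linalg.cholesky(cov)
        b = (chol @ rng.standard_normal((2, p)))  # 2 x p, rows correlated
        y = x @ b.T + 0.3 * rng.standard_normal((n, 2))
        y = np.column_stack([y, rng.standard_normal(n)])
        fit = fit_lvm(y, x, n_latent=1, seed=0)
        ec = environmental_correlations(fit, x)
        true_r = np.corrcoef(x @ b[0], x @ b[1])[0, 1]
        assert ec.corr[0, 1] == pytest.approx(true_r, abs=0.15)

    def test_bootstrap_flags_strong_pair_significant(self):
        rng = np.random.default_rng(21)
        n, p = 120, 3
        x = rng.standard_normal((n, p))
        b = np.array([[1.0, 0.5, -0.5], [0.9, 0.6, -0.4], [0.0, 0.0, 0.0]])
        y = x @ b.T + 0.3 * rng.standard_normal((n, 3))
        fit = fit_lvm(y, x, n_latent=0)
        ec = environmental_correlations(fit, x, y=y, n_bootstrap=30, seed=1)
        assert ec.significant[0, 1]

    def test_bootstrap_interval_coverage(self):
        # nominal 95% percentile intervals should cover the true pairwise
        # environmental correlation in >= 85% of simulated datasets
        covered = []
        for sim in range(20):
            rng = np.random.default_rng(100 + sim)
            n, p, d_taxa = 80, 3, 4
            x = rng.standard_normal((n, p))
            chol = np.linalg.cholesky(np.array([[1.0, 0.6], [0.6, 1.0]]))
            b12 = chol @ rng.standard_normal((2, p))
            beta = np.vstack([b12, rng.standard_normal((d_taxa - 2, p))])
            lam = 0.3 * rng.standard_normal((d_taxa, 1))
            y = (
                x @ beta.T
                + rng.standard_normal((n, 1)) @ lam.T
                + 0.3 * rng.standard_normal((n, d_taxa))
            )
            true_r = np.corrcoef(x @ beta[0], x @ beta[1])[0, 1]
            fit = fit_lvm(y, x, n_latent=1, seed=0)
            ec = environmental_correlations(
                fit, x, y=y, n_bootstrap=50, seed=sim, refit_max_iter=25
            )
            covered.append(ec.ci_low[0, 1] <= true_r <= ec.ci_high[0, 1])
        assert np.mean(covered) >= 0.85

    def test_symmetric_unit_diagonal(self):
        y, x, *_ = simulate_lvm_data(100, 6, 3, 1, 0.2, seed=9)
        fit = fit_lvm(y, x, n_latent=1, seed=0)
        ec = environmental_correlations(fit, x)
        np.testing.assert_allclose(ec.corr, ec.corr.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(ec.corr), 1.0)

    def test_per_dimension_uses_quadratic_columns(self):
        env = EnvMatrix(
            [f"s{i}" for i in range(40)],
            ["u", "v"],
            np.random.default_rng(3).standard_normal((40, 2)),
        )
        design = build_design(env, include_quadratic=True)
        y = np.column_stack(
            [
                design.values @ np.array([1.0, 0.0, 1.0, 0.0]),
                design.values @ np.array([-1.0, 0.0, 1.0, 0.0]),
            ]
        )
        fit = fit_lvm(y, design, n_latent=0)
        per_dim = environmental_correlations_per_dimension(fit, design)
        assert set(per_dim) == {"u", "v"}
        assert -1.0 < per_dim["u"][0, 1] < 1.0  # quadratic term de-degenerates


class TestResidualCorrelations:
    def test_shared_loading_no_noise_corr_one(self):
        fit = fit_lvm(np.random.default_rng(0).standard_normal((30, 3)), np.zeros((30, 0)), 0)
        fit.n_latent = 2
        fit.loadings = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        fit.sigma2 = np.zeros(3)
        rho = residual_correlations(fit)
        assert rho[0, 1] == pytest.approx(1.0)

    def test_orthogonal_loadings_zero(self):
        fit = fit_lvm(np.random.default_rng(0).standard_normal((30, 2)), np.zeros((30, 0)), 0)
        fit.n_latent = 2
        fit.loadings = np.array([[1.0, 0.0], [0.0, 1.0]])
        fit.sigma2 = np.ones(2)
        assert residual_correlations(fit)[0, 1] == pytest.approx(0.0)

    def test_large_noise_shrinks_to_zero(self):
        fit = fit_lvm(np.random.default_rng(0).standard_normal((30, 2)), np.zeros((30, 0)), 0)
        fit.n_latent = 1
        fit.loadings = np.array([[1.0], [1.0]])
        fit.sigma2 = np.array([1e8, 1e8])
        assert abs(residual_correlations(fit)[0, 1]) < 1e-6

    def test_d0_identity(self):
        y, x, *_ = simulate_lvm_data(50, 4, 2, 0, 0.2, seed=5)
        fit = fit_lvm(y, x, n_latent=0)
        np.testing.assert_array_equal(residual_correlations(fit), np.eye(4))


class TestUnivariateBestFit:
    def test_linear_selected_with_slope(self, rng):
        x = rng.standard_normal(100)
        y = 2 * x + 0.05 * rng.standard_normal(100)
        fit = univariate_best_fit(y, x)
        assert fit.degree == 1
        assert fit.coefficients[1] == pytest.approx(2.0, abs=0.05)
        # cross-check against statsmodels OLS
        ols = sm.OLS(y, sm.add_constant(x)).fit()
        np.testing.assert_allclose(fit.coefficients, ols.params, atol=1e-8)
        assert fit.adj_r2 == pytest.approx(ols.rsquared_adj, abs=1e-10)
        assert fit.fstat == pytest.approx(ols.fvalue, rel=1e-8)
        assert fit.pvalue == pytest.approx(ols.f_pvalue, abs=1e-12)

    def test_quadratic_selected(self, rng):
        x = rng.standard_normal(100)
        y = x**2 + 0.1 * rng.standard_normal(100)
        assert univariate_best_fit(y, x).degree == 2

    def test_perfect_linear_reports_degree_one(self):
        x = np.linspace(-1, 1, 20)
        fit = univariate_best_fit(3 * x + 1, x)
        assert fit.degree == 1
        assert fit.adj_r2 == pytest.approx(1.0)
        assert fit.aic == -np.inf

    def test_adjusted_r2_textbook_formula(self, rng):
        x = rng.standard_normal(40)
        y = x + rng.standard_normal(40)
        fit = fit_polynomial(x, y, 2)
        design = np.vander(x, 3, increasing=True)
        resid = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
        r2 = 1 - (resid @ resid) / ((y - y.mean()) ** 2).sum()
        expected = 1 - (1 - r2) * (40 - 1) / (40 - 2 - 1)
        assert fit.adj_r2 == pytest.approx(expected, abs=1e-10)
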