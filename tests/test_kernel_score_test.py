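"""Null model, kernel construction, score statistic, mixture p-values."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from roikst.core_data import MarkerMatrix, SampleTable
from roikst.exceptions import DataError
from roikst.kernel_score_test import (NullDistribution, build_linear_kernel,
                                      exact_ratio_pvalue, fit_null_model,
                                      kst_region_test, null_spectrum,
                                      permutation_pvalue,
                                      pvalue_mixture_chisq, score_statistic)


def _table(y, covariates=None, ids=None):
    n = len(y)
    ids = ids or tuple(f"S{i}" for i in range(n))
    cov = pd.DataFrame(covariates if covariates is not None
                       else {}, index=range(n))
    return SampleTable(sample_ids=tuple(ids), response=np.asarray(y, float),
                       covariates=cov)


def _markers(values, ids=None, kind="methylation"):
    values = np.asarray(values, float)
    n, m = values.shape
    return MarkerMatrix(
        sample_ids=tuple(f"S{i}" for i in range(n)),
        marker_ids=tuple(ids or (f"mk{j}" for j in range(m))),
        values=values, marker_kind=kind)


class TestNullModel:
    def test_intercept_only_hand_computed(self):
        # Y = (1, 2, 3): mean 2, ML variance = ((1)+(0)+(1))/3
        fit = fit_null_model(_table([1.0, 2.0, 3.0]))
        assert fit.coefficients == pytest.approx([2.0])
        assert fit.error_variance == pytest.approx(2.0 / 3.0)

    def test_reml_divisor(self):
        fit = fit_null_model(_table([1.0, 2.0, 3.0]), reml=True)
        assert fit.error_variance == pytest.approx(1.0)  # RSS / (n - 1)

    def test_intercept_recovery_with_noise(self):
        rng = np.random.default_rng(12)
        n = 1000
        cov = {"x": rng.normal(size=n)}
        y = 2.0 + rng.normal(size=n)
        fit = fit_null_model(_table(y, cov))
        assert abs(fit.coefficients[0] - 2.0) < 0.1

    def test_residuals_orthogonal_to_design(self):
        rng = np.random.default_rng(5)
        n = 50
        cov = {"a": rng.normal(size=n), "b": rng.uniform(size=n)}
        fit = fit_null_model(_table(rng.normal(size=n), cov))
        assert np.abs(fit.design.T @ fit.residuals).max() < 1e-8 * n

    def test_exact_fit_is_degenerate_error(self):
        x = np.arange(5.0)
        with pytest.raises(DataError):
            fit_null_model(_table(2.0 * x, {"x": x}))

    def test_collinear_column_named(self):
        x = np.arange(6.0)
        with pytest.raises(DataError, match="x[12]"):
            fit_null_model(_table(np.random.default_rng(0).normal(size=6),
                                  {"x1": x, "x2": 2.0 * x}))


class TestLinearKernel:
    def test_identity_z_gives_identity_kernel(self):
        K = build_linear_kernel(_markers(np.eye(2)), centering=False)
        np.testing.assert_array_equal(K.K, np.eye(2))

    def test_single_column_outer_product(self):
        K = build_linear_kernel(_markers([[1.0], [2.0]], kind="genotype"),
                                centering=False, region_name="r")
        np.testing.assert_array_equal(K.K, [[1.0, 2.0], [2.0, 4.0]])

    def test_constant_column_annihilated_by_centering(self):
        Z = np.column_stack([np.full(4, 0.7), [0.1, 0.2, 0.3, 0.4]])
        K_with = build_linear_kernel(_markers(Z), centering=True)
        K_wo = build_linear_kernel(
            _markers(Z[:, 1:], ids=["mk1"]), centering=True)
        np.testing.assert_allclose(K_with.K, K_wo.K, atol=1e-15)

    def test_symmetry_and_psd(self, toy_markers):
        K = build_linear_kernel(toy_markers)
        assert np.array_equal(K.K, K.K.T)
        assert np.linalg.eigvalsh(K.K)[0] >= -1e-8 * np.abs(K.K).max()


class TestScoreStatistic:
    def _instance(self, seed=9, n=20, m=4):
        rng = np.random.default_rng(seed)
        table = _table(rng.normal(size=n),
                       {"c": rng.normal(size=n)},
                       ids=[f"S{i}" for i in range(n)])
        Z = _markers(rng.beta(2, 2, size=(n, m)))
        return table, Z

    def test_zero_residuals_zero_statistic(self):
        table, Z = self._instance()
        null = fit_null_model(table)
        K = build_linear_kernel(Z)
        object.__setattr__(null, "residuals", np.zeros(table.n))
        assert score_statistic(null, K) == 0.0

    def test_identity_kernel_is_scaled_rss(self):
        table, Z = self._instance(n=6, m=6)
        null = fit_null_model(table)
        K = build_linear_kernel(_markers(np.eye(6)), centering=False)
        rss = float(null.residuals @ null.residuals)
        assert score_statistic(null, K) == pytest.approx(
            rss / (2 * null.error_variance))

    def test_full_and_factorized_forms_agree(self):
        """r'Kr and ||Z''r||^2 are algebraically identical."""
        table, Z = self._instance()
        null = fit_null_model(table)
        K = build_linear_kernel(Z)
        q_fact = score_statistic(null, K)
        q_full = float(null.residuals @ K.K @ null.residuals) / (
            2 * null.error_variance)
        assert q_fact == pytest.approx(q_full, rel=1e-10)

    def test_duplicated_marker_adds_outer_product(self):
        table, Z = self._instance(m=3)
        null = fit_null_model(table)
        K1 = build_linear_kernel(Z, centering=False)
        Zdup = _markers(np.column_stack([Z.values, Z.values[:, [0]]]))
        K2 = build_linear_kernel(Zdup, centering=False)
        z = Z.values[:, [0]]
        np.testing.assert_allclose(K2.K, K1.K + z @ z.T, atol=1e-12)
        q2 = score_statistic(null, K2)
        extra = float((z[:, 0] @ null.residuals) ** 2) / (
            2 * null.error_variance)
        assert q2 == pytest.approx(score_statistic(null, K1) + extra,
                                   rel=1e-10)


class TestNullSpectrum:
    def test_single_marker_single_eigenvalue(self):
        rng = np.random.default_rng(2)
        table = _table(rng.normal(size=10))
        null = fit_null_model(table)
        K = build_linear_kernel(_markers(rng.beta(2, 2, size=(10, 1))))
        dist = null_spectrum(null, K)
        assert dist.k == 1

    def test_covariate_marker_degenerate(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0.1, 0.9, size=10)
        table = _table(rng.normal(size=10), {"x": x})
        null = fit_null_model(table)
        K = build_linear_kernel(_markers(x[:, None]), centering=True)
        dist = null_spectrum(null, K)
        assert dist.k == 0

    def test_gram_and_projected_kernel_routes_agree(self):
        """m x m Gram spectrum equals the n x n projected-kernel spectrum."""
        rng = np.random.default_rng(30)
        n, m = 30, 4
        table = _table(rng.normal(size=n), {"c": rng.normal(size=n)})
        null = fit_null_model(table)
        K = build_linear_kernel(_markers(rng.beta(2, 2, size=(n, m))))
        dist = null_spectrum(null, K)  # m < n: Gram route
        X = null.design
        P = np.eye(n) - X @ np.linalg.pinv(X)
        w = np.linalg.eigvalsh(P @ K.K @ P) / 2.0
        w = np.sort(w)[::-1][:dist.k]
        np.testing.assert_allclose(dist.eigenvalues, w, rtol=1e-8,
                                   atol=1e-10)

    def test_spectrum_bounded_by_rank(self):
        rng = np.random.default_rng(8)
        n, m = 15, 6
        table = _table(rng.normal(size=n), {"c": rng.normal(size=n)})
        null = fit_null_model(table)
        K = build_linear_kernel(_markers(rng.beta(2, 2, size=(n, m))))
        dist = null_spectrum(null, K)
        assert dist.k <= min(n - null.p, m)


class TestMixturePvalue:
    @pytest.mark.parametrize("df", [1, 2])
    def test_chi2_quantiles(self, df):
        q = float(stats.chi2.ppf(0.95, df))
        p, method = pvalue_mixture_chisq(
            q, NullDistribution(np.ones(df), 0.0))
        assert p == pytest.approx(0.05, abs=1e-4)
        assert method == "davies"

    def test_monte_carlo_oracle(self):
        lam = np.array([2.0, 1.0])
        q = 7.0
        rng = np.random.default_rng(77)
        draws = (lam * rng.chisquare(1, size=(200_000, 2))).sum(axis=1)
        p_mc = float(np.mean(draws > q))
        se = np.sqrt(p_mc * (1 - p_mc) / draws.shape[0] * 1.0)
        p, _ = pvalue_mixture_chisq(q, NullDistribution(lam, 0.0))
        assert abs(p - p_mc) < 3 * se

    def test_wide_spectrum_stays_davies(self):
        lam = np.array([1.0, 1e-3, 1e-6, 1e-9])
        p, method = pvalue_mixture_chisq(5.0, NullDistribution(lam, 0.0))
        assert method == "davies"
        assert 0.0 <= p <= 1.0

    def test_zero_statistic(self):
        p, _ = pvalue_mixture_chisq(0.0, NullDistribution(np.ones(2), 0.0))
        assert p == 1.0

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            pvalue_mixture_chisq(np.nan, NullDistribution(np.ones(1), 0.0))


class TestExactRatioPvalue:
    def test_single_marker_equals_t_test(self):
        """m = 1: the exact kernel p equals the regression t-test p."""
        from roikst.interaction_model import fit_single_marker_regression
        rng = np.random.default_rng(17)
        n = 40
        table = _table(rng.normal(size=n), {"c": rng.normal(size=n)})
        Z = _markers(rng.beta(2, 2, size=(n, 1)))
        res = kst_region_test(table, Z)
        p_t = fit_single_marker_regression(table, Z).p("marker")
        assert res.p_value == pytest.approx(p_t, rel=1e-9)

    def test_large_n_matches_plugin_mixture(self):
        """Variance estimation is negligible at large n: the exact and
        plug-in tails converge."""
        rng = np.random.default_rng(23)
        n = 4000
        table = _table(rng.normal(size=n), {"c": rng.normal(size=n)})
        Z = _markers(rng.beta(2, 2, size=(n, 3)))
        null = fit_null_model(table)
        K = build_linear_kernel(Z)
        q = score_statistic(null, K)
        dist = null_spectrum(null, K)
        p_exact, ok = exact_ratio_pvalue(dist, n - null.p, q, n)
        assert ok
        p_plug, _ = pvalue_mixture_chisq(q, dist)
        assert p_exact == pytest.approx(p_plug, abs=2e-3)


class TestRegionTest:
    def test_marker_order_invariance(self, toy_table, toy_markers):
        res = kst_region_test(toy_table, toy_markers)
        shuffled = toy_markers.restrict_markers(["cgZ", "cgX", "cgY"])
        res2 = kst_region_test(toy_table, shuffled)
        assert res2.Q == pytest.approx(res.Q, rel=1e-12)
        assert res2.p_value == pytest.approx(res.p_value, rel=1e-9)

    def test_joint_sample_permutation_invariance(self, toy_table,
                                                 toy_markers):
        res = kst_region_test(toy_table, toy_markers)
        rng = np.random.default_rng(1)
        order = rng.permutation(toy_table.n)
        ids = tuple(toy_table.sample_ids[i] for i in order)
        table2 = SampleTable(
            sample_ids=ids, response=toy_table.response[order],
            covariates=toy_table.covariates.iloc[order].reset_index(
                drop=True))
        markers2 = toy_markers.restrict_samples(ids)
        res2 = kst_region_test(table2, markers2)
        assert res2.p_value == pytest.approx(res.p_value, rel=1e-9)

    def test_misaligned_rows_rejected(self, toy_table, toy_markers):
        bad = toy_markers.restrict_samples(toy_table.sample_ids[::-1])
        with pytest.raises(DataError):
            kst_region_test(toy_table, bad)

    def test_centering_irrelevant_with_intercept(self, toy_table,
                                                 toy_markers):
        p_on = kst_region_test(toy_table, toy_markers, centering=True)
        p_off = kst_region_test(toy_table, toy_markers, centering=False)
        assert p_on.p_value == pytest.approx(p_off.p_value, rel=1e-8)


class TestPermutation:
    def test_add_one_floor(self, toy_table, toy_markers):
        p = permutation_pvalue(toy_table, toy_markers, n_perm=999, seed=0)
        assert p >= 1.0 / 1000

    def test_agrees_with_analytic(self):
        rng = np.random.default_rng(44)
        n = 60
        table = _table(rng.normal(size=n), {"c": rng.normal(size=n)})
        Z = _markers(rng.beta(2, 2, size=(n, 3)))
        res = kst_region_test(table, Z)
        p_perm = permutation_pvalue(table, Z, n_perm=4000, seed=9)
        se = np.sqrt(p_perm * (1 - p_perm) / 4000)
        assert abs(res.p_value - p_perm) < 4 * se

    def test_deterministic_under_seed(self, toy_table, toy_markers):
        p1 = permutation_pvalue(toy_table, toy_markers, n_perm=500, seed=5)
        p2 = permutation_pvalue(toy_table, toy_markers, n_perm=500, seed=5)
        assert p1 == p2
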