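"""Null models, score statistic, mixture weights and the full region test."""

import numpy as np
import pytest

from recwas.exceptions import DegenerateDataError, ParameterError
from recwas.kernels import build_kernel, kernel_features
from recwas.score_test import (fit_null_model, null_mixture_weights,
                               recwas_test, score_statistic)
from recwas.simulate import simulate_genotypes


class TestNullModel:
    def test_intercept_only_continuous_fits_mean(self):
        Y = np.arange(12, dtype=float)
        nm = fit_null_model(Y)
        np.testing.assert_allclose(nm.fitted, np.full(12, Y.mean()))
        assert nm.trait_type == "continuous"

    def test_residuals_orthogonal_to_covariates(self, rng):
        Z = rng.standard_normal((50, 3))
        Y = Z @ np.array([1.0, -2.0, 0.5]) + rng.standard_normal(50)
        nm = fit_null_model(Y, covariates=Z)
        np.testing.assert_allclose(nm.design.T @ nm.residuals,
                                   np.zeros(4), atol=1e-8)

    def test_dichotomous_prevalence(self):
        Y = np.array([1.0] * 3 + [0.0] * 7)
        nm = fit_null_model(Y, trait_type="dichotomous")
        np.testing.assert_allclose(nm.fitted, np.full(10, 0.3))

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateDataError):
            fit_null_model(np.ones(12), trait_type="dichotomous")

    def test_collinear_covariates_rejected(self, rng):
        z = rng.standard_normal(20)
        with pytest.raises(ParameterError):
            fit_null_model(rng.standard_normal(20),
                           covariates=np.column_stack([z, 2 * z]))

    def test_saturated_null_gives_zero_statistic(self, rng):
        Y = rng.standard_normal(30)
        nm = fit_null_model(Y, covariates=Y)
        G = rng.integers(0, 3, size=(30, 4)).astype(float)
        K = build_kernel(G, None, "linear")
        assert score_statistic(nm, K) == pytest.approx(0.0, abs=1e-18)


class TestScoreStatistic:
    def test_identity_kernel_gives_residual_sum_of_squares(self, rng):
        Y = rng.standard_normal(25)
        nm = fit_null_model(Y)
        from recwas.kernels import KernelMatrix
        q = score_statistic(nm, KernelMatrix(np.eye(25), "linear"))
        assert q == pytest.approx(float(nm.residuals @ nm.residuals))

    def test_double_loop_oracle(self, rng):
        Y = rng.standard_normal(15)
        nm = fit_null_model(Y)
        G = rng.integers(0, 3, size=(15, 4)).astype(float)
        K = build_kernel(G, None, "IBS").K
        r = nm.residuals
        brute = sum(r[i] * K[i, j] * r[j]
                    for i in range(15) for j in range(15))
        from recwas.kernels import KernelMatrix
        assert score_statistic(nm, KernelMatrix(K, "IBS")) == pytest.approx(
            brute, abs=1e-10)

    def test_feature_and_kernel_routes_agree(self, rng):
        Y = rng.standard_normal(20)
        nm = fit_null_model(Y)
        G = rng.integers(0, 3, size=(20, 3)).astype(float)
        w = rng.normal(size=3)
        A = kernel_features(G, w, "weighted_linear")
        K = build_kernel(G, w, "weighted_linear")
        assert score_statistic(nm, A) == pytest.approx(
            score_statistic(nm, K), rel=1e-10)

    def test_dimension_mismatch(self, rng):
        nm = fit_null_model(rng.standard_normal(20))
        from recwas.kernels import KernelMatrix
        with pytest.raises(ParameterError):
            score_statistic(nm, KernelMatrix(np.eye(5), "linear"))


class TestMixtureWeights:
    def test_identity_kernel_centering_eigenstructure(self, rng):
        # intercept-only null, K = I: (I-H) has n-1 unit eigenvalues
        Y = rng.standard_normal(30)
        nm = fit_null_model(Y)
        from recwas.kernels import KernelMatrix
        lam = null_mixture_weights(nm, KernelMatrix(np.eye(30), "linear"))
        assert lam.size == 29
        np.testing.assert_allclose(lam, nm.dispersion, rtol=1e-10)

    def test_rank_one_kernel(self, rng):
        Y = rng.standard_normal(25)
        nm = fit_null_model(Y)
        g = rng.standard_normal((25, 1))
        from recwas.kernels import KernelMatrix
        lam = null_mixture_weights(nm, KernelMatrix(g @ g.T, "linear"))
        assert lam.size == 1

    def test_trace_identity(self, rng):
        Y = rng.standard_normal(40)
        Z = rng.standard_normal((40, 2))
        nm = fit_null_model(Y, covariates=Z)
        G = rng.integers(0, 3, size=(40, 5)).astype(float)
        K = build_kernel(G, None, "IBS").K
        D = nm.design
        H = D @ np.linalg.solve(D.T @ D, D.T)
        M = nm.dispersion * (np.eye(40) - H) @ K @ (np.eye(40) - H)
        from recwas.kernels import KernelMatrix
        lam = null_mixture_weights(nm, KernelMatrix(K, "IBS"))
        assert lam.sum() == pytest.approx(np.trace(M), rel=1e-8)

    def test_feature_route_matches_kernel_route(self, rng):
        for trait in ("continuous", "dichotomous"):
            if trait == "continuous":
                Y = rng.standard_normal(30)
            else:
                Y = (rng.uniform(size=30) < 0.4).astype(float)
            Z = rng.standard_normal((30, 2))
            nm = fit_null_model(Y, covariates=Z, trait_type=trait)
            G = rng.integers(0, 3, size=(30, 4)).astype(float)
            w = rng.normal(size=4)
            lam_a = null_mixture_weights(
                nm, kernel_features(G, w, "weighted_linear"))
            lam_k = null_mixture_weights(
                nm, build_kernel(G, w, "weighted_linear"))
            np.testing.assert_allclose(lam_a, lam_k, rtol=1e-7, atol=1e-10)


class TestRecwasTest:
    def _data(self, seed=0, n=200, p=6):
        rng = np.random.default_rng(seed)
        ds = simulate_genotypes(n, p, seed=seed)
        w = rng.normal(size=p)
        Y = rng.standard_normal(n)
        return ds.matrix, w, Y

    def test_deterministic(self):
        G, w, Y = self._data()
        r1 = recwas_test(G, w, Y)
        r2 = recwas_test(G, w, Y)
        assert r1.p_value == r2.p_value and r1.statistic == r2.statistic

    def test_sample_reordering_invariance(self, rng):
        G, w, Y = self._data(1)
        perm = rng.permutation(len(Y))
        r1 = recwas_test(G, w, Y)
        r2 = recwas_test(G[perm], w, Y[perm])
        assert r2.p_value == pytest.approx(r1.p_value, rel=1e-8)

    def test_weight_rescaling_invariance(self):
        G, w, Y = self._data(2)
        r1 = recwas_test(G, w, Y)
        r2 = recwas_test(G, 7.3 * w, Y)
        assert r2.p_value == pytest.approx(r1.p_value, rel=1e-8)

    def test_all_zero_weights_untestable(self):
        G, w, Y = self._data(3)
        res = recwas_test(G, np.zeros_like(w), Y)
        assert not res.testable and np.isnan(res.p_value)

    def test_maf_filter_can_empty_the_region(self, rng):
        G = np.zeros((50, 2))
        G[0, 0] = 1.0  # MAF 0.01, below the common-variant cutoff
        res = recwas_test(G, np.array([1.0, 1.0]), rng.standard_normal(50))
        assert not res.testable and res.n_snps_used == 0

    def test_weight_power_option_changes_statistic(self):
        G, w, Y = self._data(4)
        r2 = recwas_test(G, w, Y, weight_power=2)
        r4 = recwas_test(G, w, Y, weight_power=4)
        assert r2.statistic != pytest.approx(r4.statistic)

    def test_ibs_kernel_runs_end_to_end(self):
        G, w, Y = self._data(5)
        res = recwas_test(G, w, Y, kernel_name="weighted_IBS")
        assert res.testable and 0 < res.p_value <= 1
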