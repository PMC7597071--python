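"""The weighted LMM engine against closed forms and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mbmm.lmm import (LMMProblem, ar1_correlation_matrix,
                      cs_correlation_matrix, fit_weighted_lmm, wald_table)
from oracles import lmm_direct_mle


class TestCorrelationMatrices:
    def test_ar1_zero_rho_identity(self):
        np.testing.assert_array_equal(ar1_correlation_matrix([0, 1, 2], 0.0),
                                      np.eye(3))

    def test_ar1_powers(self):
        R = ar1_correlation_matrix([0, 1, 2], 0.5)
        np.testing.assert_allclose(R[0], [1.0, 0.5, 0.25])
        np.testing.assert_allclose(R[1], [0.5, 1.0, 0.5])

    def test_ar1_singleton(self):
        np.testing.assert_array_equal(ar1_correlation_matrix([0], 0.7), [[1.0]])

    def test_ar1_domain(self):
        with pytest.raises(ValueError):
            ar1_correlation_matrix([0, 1], 1.0)

    def test_cs_structure(self):
        R = cs_correlation_matrix(3, 0.3)
        assert R[0, 1] == R[0, 2] == pytest.approx(0.3)
        np.testing.assert_allclose(np.diag(R), 1.0)


class TestClosedForms:
    def test_singleton_groups_reduce_to_wls(self, rng):
        """With one observation per subject the random effect is
        unidentifiable and the GLS estimate must equal weighted least
        squares."""
        n = 40
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = X @ [1.0, 0.5] + rng.normal(size=n)
        prob = LMMProblem(y=y, X=X, groups=np.arange(n), Z=np.ones((n, 1)))
        fit = fit_weighted_lmm(prob)
        beta_ols = np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(fit.beta, beta_ols, atol=1e-6)

    def test_balanced_anova_reml(self, rng):
        """Balanced one-way layout: REML variance components equal the
        ANOVA closed forms sigma2=MSW, psi=(MSB-MSW)/k."""
        g, k = 10, 4
        b = rng.normal(0, 0.8, g)
        y = 1.5 + np.repeat(b, k) + rng.normal(0, 1.0, g * k)
        prob = LMMProblem(y=y, X=np.ones((g * k, 1)),
                          groups=np.repeat(np.arange(g), k),
                          Z=np.ones((g * k, 1)))
        fit = fit_weighted_lmm(prob, method="REML")
        Y = y.reshape(g, k)
        msw = np.sum((Y - Y.mean(1, keepdims=True)) ** 2) / (g * (k - 1))
        msb = k * np.sum((Y.mean(1) - y.mean()) ** 2) / (g - 1)
        assert fit.sigma2 == pytest.approx(msw, rel=1e-5)
        assert fit.psi[0, 0] == pytest.approx(max((msb - msw) / k, 0), rel=1e-4)
        assert fit.beta[0] == pytest.approx(y.mean(), abs=1e-10)

    def test_constant_response_degenerate(self):
        y = np.full(12, 3.0)
        prob = LMMProblem(y=y, X=np.ones((12, 1)),
                          groups=np.repeat(np.arange(4), 3),
                          Z=np.ones((12, 1)))
        fit = fit_weighted_lmm(prob)
        assert fit.beta[0] == pytest.approx(3.0, abs=1e-8)
        assert fit.sigma2 < 1e-6


class TestBruteForceOracle:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_small_instance_matches_direct_ml(self, seed):
        """<=12 observations: profiled-likelihood fit agrees with direct
        numerical maximization of the explicit marginal likelihood."""
        rng = np.random.default_rng(seed)
        g, k = 4, 3
        groups = np.repeat(np.arange(g), k)
        X = np.column_stack([np.ones(g * k), rng.normal(size=g * k)])
        Z = np.ones((g * k, 1))
        y = X @ [1.0, 0.7] + np.repeat(rng.normal(0, 0.6, g), k) \
            + rng.normal(0, 0.8, g * k)
        fit = fit_weighted_lmm(LMMProblem(y=y, X=X, groups=groups, Z=Z),
                               method="ML")
        beta_o, psi_o, s2_o, ll_o = lmm_direct_mle(y, X, Z, groups, reml=False)
        np.testing.assert_allclose(fit.beta, beta_o, rtol=1e-4, atol=1e-6)
        assert fit.sigma2 == pytest.approx(s2_o, rel=1e-3, abs=1e-5)
        assert fit.psi[0, 0] == pytest.approx(psi_o[0, 0], rel=1e-3, abs=1e-4)
        assert fit.loglik == pytest.approx(ll_o, abs=1e-5)

    def test_ar1_beats_or_matches_independence_likelihood(self, rng):
        """Fitting with AR(1) must not lose likelihood relative to rho=0
        on data with autocorrelated residuals."""
        g, k = 12, 6
        groups = np.repeat(np.arange(g), k)
        eps = rng.normal(size=(g, k))
        for j in range(1, k):
            eps[:, j] = 0.7 * eps[:, j - 1] + np.sqrt(1 - 0.49) * eps[:, j]
        y = 1.0 + np.repeat(rng.normal(0, 0.5, g), k) + eps.ravel()
        X = np.ones((g * k, 1))
        Z = np.ones((g * k, 1))
        f_ind = fit_weighted_lmm(LMMProblem(y=y, X=X, groups=groups, Z=Z),
                                 method="ML")
        f_ar = fit_weighted_lmm(
            LMMProblem(y=y, X=X, groups=groups, Z=Z, correlation="ar1"),
            method="ML")
        assert f_ar.loglik >= f_ind.loglik - 1e-6
        assert 0.3 < f_ar.rho < 0.95


class TestWaldTable:
    def test_normal_reference(self):
        from mbmm.lmm import LMMFit
        fit = LMMFit(beta=np.array([0.5, 0.0]), beta_cov=np.diag([0.0625, 1.0]),
                     psi=np.zeros((0, 0)), sigma2=1.0, rho=0.0, loglik=0.0,
                     fitted=np.zeros(1), x_names=["a", "b"])
        tab = wald_table(fit)
        assert tab.loc["a", "statistic"] == pytest.approx(2.0)
        assert tab.loc["a", "pvalue"] == pytest.approx(0.045500, abs=1e-5)
        assert tab.loc["b", "pvalue"] == pytest.approx(1.0)

    def test_zero_se_nonzero_estimate(self):
        from mbmm.lmm import LMMFit
        fit = LMMFit(beta=np.array([1.0]), beta_cov=np.zeros((1, 1)),
                     psi=np.zeros((0, 0)), sigma2=1.0, rho=0.0, loglik=0.0,
                     fitted=np.zeros(1), x_names=["a"])
        with pytest.warns(UserWarning):
            tab = wald_table(fit)
        assert tab.loc["a", "pvalue"] == 0.0


class TestInvariances:
    @given(st.floats(min_value=0.2, max_value=5.0))
    @settings(max_examples=10, deadline=None, derandomize=True)
    def test_uniform_weight_rescaling_leaves_beta(self, c):
        rng = np.random.default_rng(99)
        g, k = 8, 4
        groups = np.repeat(np.arange(g), k)
        X = np.column_stack([np.ones(g * k), rng.normal(size=g * k)])
        w = rng.uniform(0.5, 2.0, g * k)
        y = X @ [1.0, 0.4] + np.repeat(rng.normal(0, 0.5, g), k) \
            + rng.normal(size=g * k) / np.sqrt(w)
        f1 = fit_weighted_lmm(LMMProblem(y=y, X=X, groups=groups,
                                         Z=np.ones((g * k, 1)), weights=w))
        f2 = fit_weighted_lmm(LMMProblem(y=y, X=X, groups=groups,
                                         Z=np.ones((g * k, 1)), weights=c * w))
        np.testing.assert_allclose(f1.beta, f2.beta, rtol=1e-4, atol=1e-6)

    def test_aliased_column_dropped_with_warning(self, rng):
        g, k = 6, 3
        groups = np.repeat(np.arange(g), k)
        X = np.column_stack([np.ones(g * k), np.zeros(g * k)])
        y = 1.0 + rng.normal(size=g * k)
        fit = fit_weighted_lmm(
            LMMProblem(y=y, X=X, groups=groups, Z=np.ones((g * k, 1)),
                       x_names=["Intercept", "dead"]))
        assert "dead" in fit.aliased
        assert len(fit.beta) == 1
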