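"""Sampler component tests: the exact coefficient draw, the truncated
inverse-gamma primitive, conditional-conjugacy oracles, a quadrature oracle
for the Bayesian LASSO, and behavioral recovery checks."""

import numpy as np
import pytest
from scipy import stats

from sparsebench.methods_bayes import (
    BayesianLasso,
    Horseshoe,
    HorseshoePlus,
    McmcConfig,
    RegularizedHorseshoe,
    _inv_gamma,
    _trunc_inv_gamma,
    draw_coefficients,
    fit_blasso,
    fit_horseshoe,
    fit_horseshoe_plus,
    fit_reg_horseshoe,
    regularized_local_variance,
)


class TestDrawCoefficients:
    def test_fast_equals_direct_given_innovations(self, rng):
        n, p = 30, 10
        X = rng.standard_normal((n, p))
        y = rng.standard_normal(n)
        v = rng.uniform(0.1, 2.0, p)
        z = rng.standard_normal(p)
        f = rng.standard_normal(n)
        a = draw_coefficients(X, y, v, 1.3, innovations=(z, f), method="direct")
        b = draw_coefficients(X, y, v, 1.3, innovations=(z, f), method="fast")
        np.testing.assert_allclose(a, b, rtol=1e-9, atol=1e-11)

    def test_moments_match_exact_posterior(self, rng):
        n, p = 40, 3
        X = rng.standard_normal((n, p))
        beta_true = np.array([1.0, -1.0, 0.0])
        sigma2 = 0.5
        y = X @ beta_true + np.sqrt(sigma2) * rng.standard_normal(n)
        v = np.array([0.5, 1.0, 2.0])
        A = X.T @ X / sigma2 + np.diag(1.0 / v)
        cov = np.linalg.inv(A)
        mean = cov @ (X.T @ y) / sigma2
        draws = np.array([draw_coefficients(X, y, v, sigma2, rng) for _ in range(20000)])
        se = np.sqrt(np.diag(cov) / 20000)
        assert np.all(np.abs(draws.mean(axis=0) - mean) < 4 * se)
        assert np.allclose(np.cov(draws.T), cov, atol=4 * np.max(np.diag(cov)) / np.sqrt(20000))

    def test_zero_prior_variance_pins_beta(self, rng):
        X = rng.standard_normal((10, 4))
        y = rng.standard_normal(10)
        out = draw_coefficients(X, y, np.zeros(4), 1.0, rng)
        np.testing.assert_array_equal(out, np.zeros(4))


class TestTruncatedInverseGamma:
    def test_unconstrained_matches_scipy(self, rng):
        draws = np.array([_trunc_inv_gamma(2.0, 3.0, rng) for _ in range(8000)])
        ks = stats.kstest(draws, stats.invgamma(2.0, scale=3.0).cdf)
        assert ks.statistic < 0.02

    def test_lower_truncation_distribution(self, rng):
        a, b, lo = 1.0, 2.0, 1.5
        draws = np.array([_trunc_inv_gamma(a, b, rng, lower=lo) for _ in range(8000)])
        assert draws.min() >= lo
        dist = stats.invgamma(a, scale=b)
        flo = dist.cdf(lo)
        u = (dist.cdf(draws) - flo) / (1 - flo)
        assert stats.kstest(u, "uniform").statistic < 0.02

    def test_upper_truncation_distribution(self, rng):
        a, b, hi = 2.0, 1.0, 0.8
        draws = np.array([_trunc_inv_gamma(a, b, rng, upper=hi) for _ in range(8000)])
        assert draws.max() <= hi
        dist = stats.invgamma(a, scale=b)
        u = dist.cdf(draws) / dist.cdf(hi)
        assert stats.kstest(u, "uniform").statistic < 0.02

    def test_vectorized_lower(self, rng):
        lo = np.array([0.0, 0.5, 2.0])
        draws = _trunc_inv_gamma(1.0, np.array([1.0, 1.0, 1.0]), rng, lower=lo, size=3)
        assert np.all(draws >= lo)


class TestConditionalConjugacy:
    """Each implemented full conditional, iterated with everything else held
    fixed, must reproduce its closed-form density (KS check)."""

    def test_horseshoe_local_scale_conditional(self, rng):
        # lam_j^2 | . ~ IG(1, 1/nu + b^2/(2 tau^2 sigma^2))
        nu, b2, tau2, sigma2 = 0.7, 0.4, 0.3, 1.2
        scale = 1.0 / nu + b2 / (2 * tau2 * sigma2)
        draws = _inv_gamma(1.0, scale, rng, size=20000)
        ks = stats.kstest(draws, stats.invgamma(1.0, scale=scale).cdf)
        assert ks.statistic < 0.02

    def test_blasso_mixing_conditional_is_wald(self, rng):
        # 1/t_j^2 | . ~ InverseGaussian(sqrt(l^2 s^2 / b^2), l^2)
        lam2, sigma2, b = 4.0, 1.0, 0.5
        mu = np.sqrt(lam2 * sigma2 / b**2)
        draws = rng.wald(mu, lam2, size=20000)
        ks = stats.kstest(draws, stats.invgauss(mu / lam2, scale=lam2).cdf)
        assert ks.statistic < 0.02

    def test_sigma2_conditional_stationary(self, rng):
        """Iterating only the sigma^2 update at fixed beta reproduces
        IG((n+p)/2, (RSS + quad)/2)."""
        n, p = 15, 4
        X = rng.standard_normal((n, p))
        y = rng.standard_normal(n)
        hs = Horseshoe()
        from sparsebench.methods_bayes import ShrinkageState

        st = ShrinkageState(beta=np.full(p, 0.3), sigma2=1.0, tau2=0.5,
                            lam2=np.ones(p), nu=np.ones(p))
        draws = []
        for _ in range(20000):
            hs._update_sigma2(st, X, y, st.tau2 * st.lam2, rng)
            draws.append(st.sigma2)
        rss = float(np.sum((y - X @ st.beta) ** 2))
        quad = float(np.sum(st.beta**2 / (st.tau2 * st.lam2)))
        dist = stats.invgamma((n + p) / 2, scale=(rss + quad) / 2)
        assert stats.kstest(np.array(draws), dist.cdf).statistic < 0.02


class TestBayesianLassoOracle:
    def test_p1_quadrature_oracle(self):
        """With p = 1, fixed penalty and fixed sigma^2, the Gibbs posterior
        mean of beta matches 2-D numerical integration over (beta, t^2)."""
        r = np.random.default_rng(5)
        n = 25
        x = r.standard_normal(n)
        x = (x - x.mean()) / x.std()
        y = 0.8 * x + r.standard_normal(n)
        y = y - y.mean()
        X = x[:, None]
        lam2, sigma2 = 4.0, 1.0

        betas = np.linspace(-2, 3, 801)
        t2s = np.linspace(1e-4, 30, 1201)
        B, T = np.meshgrid(betas, t2s, indexing="ij")
        loglik = -0.5 * np.sum((y[None, None, :] - B[..., None] * x[None, None, :]) ** 2, axis=-1) / sigma2
        logprior = -0.5 * B**2 / (sigma2 * T) - 0.5 * np.log(T) - (lam2 / 2) * T
        logpost = loglik + logprior
        w = np.exp(logpost - logpost.max())
        post_mean = float(np.sum(w * B) / np.sum(w))

        res = fit_blasso(
            X, y, McmcConfig(n_iter=30000, burn_in=2000, seed=4),
            lambda2_fixed=lam2, sigma2_fixed=sigma2,
        )
        assert res.posterior_mean[0] == pytest.approx(post_mean, abs=0.01)


class TestSamplerBehavior:
    def test_null_data_calibration(self, toy_regression):
        X, y, _ = toy_regression(n=100, p=5, support=[], beta_vals=[], sigma=1.0, seed=8)
        mc = McmcConfig(n_iter=3000, burn_in=500, seed=2)
        for fit in (fit_blasso, fit_horseshoe, fit_horseshoe_plus):
            res = fit(X, y, mc)
            # all posterior means within ~3 posterior sds of zero
            assert np.all(np.abs(res.posterior_mean) < 3 * 1.0 / np.sqrt(100) * 2)

    def test_horseshoe_recovers_strong_signal(self, toy_regression):
        X, y, _ = toy_regression(n=200, p=50, support=[0], beta_vals=[10.0],
                                 sigma=1.0, seed=9)
        res = fit_horseshoe(X, y, McmcConfig(n_iter=3000, burn_in=500, seed=3))
        assert res.posterior_mean[0] == pytest.approx(10.0, rel=0.1)
        assert np.max(np.abs(res.posterior_mean[1:])) < 0.1

    def test_tau_zero_limit_pins_beta(self, toy_regression):
        X, y, _ = toy_regression(n=50, p=8, support=[0], beta_vals=[5.0], sigma=1.0, seed=10)
        res = fit_horseshoe(
            X, y, McmcConfig(n_iter=200, burn_in=50, seed=1), tau2_fixed=0.0
        )
        np.testing.assert_array_equal(res.posterior_mean, np.zeros(8))

    def test_fixed_seed_identical_chain(self, toy_regression):
        X, y, _ = toy_regression(n=40, p=6, support=[1], beta_vals=[2.0], sigma=1.0, seed=11)
        mc = McmcConfig(n_iter=500, burn_in=100, seed=42)
        a = fit_horseshoe(X, y, mc)
        b = fit_horseshoe(X, y, mc)
        np.testing.assert_array_equal(a.posterior_mean, b.posterior_mean)

    def test_hsp_frozen_eta_matches_horseshoe_conditionals(self, toy_regression):
        """With eta frozen at 1 the horseshoe+ chain is the horseshoe chain."""
        X, y, _ = toy_regression(n=40, p=6, support=[0], beta_vals=[3.0], sigma=1.0, seed=12)
        n, p = X.shape
        rng_a = np.random.default_rng(5)
        rng_b = np.random.default_rng(5)
        hs = Horseshoe()
        hsp = HorseshoePlus(eta_fixed=1.0)
        sa = hs.init_state(n, p, rng_a)
        sb = hsp.init_state(n, p, rng_b)
        for _ in range(50):
            sa = hs.step(sa, X, y, rng_a)
            sb = hsp.step(sb, X, y, rng_b)
        np.testing.assert_allclose(sa.beta, sb.beta, rtol=1e-12)
        np.testing.assert_allclose(sa.lam2, sb.lam2, rtol=1e-12)
        assert sa.tau2 == pytest.approx(sb.tau2, rel=1e-12)

    def test_hsp_shrinks_large_effects_less(self, toy_regression):
        """Heavier tails: the horseshoe+ posterior mean of a strong signal
        is at least the horseshoe's on average over seeds."""
        diffs = []
        for seed in range(8):
            X, y, _ = toy_regression(n=60, p=10, support=[0], beta_vals=[4.0],
                                     sigma=1.0, seed=100 + seed)
            mc = McmcConfig(n_iter=1500, burn_in=300, seed=seed)
            hs = fit_horseshoe(X, y, mc).posterior_mean[0]
            hsp = fit_horseshoe_plus(X, y, mc).posterior_mean[0]
            diffs.append(abs(hsp) - abs(hs))
        assert np.mean(diffs) > -0.01


class TestRegularizedHorseshoe:
    def test_tau0_formula(self):
        s = RegularizedHorseshoe(p0=10, n=200)
        assert s.tau02 == pytest.approx(10 / 190)

    def test_p0_bounds(self):
        with pytest.raises(ValueError):
            RegularizedHorseshoe(p0=200, n=200)
        with pytest.raises(ValueError):
            RegularizedHorseshoe(p0=0, n=200)

    def test_c_infinity_recovers_plain_local_variance(self):
        lam2 = np.array([0.5, 2.0, 10.0])
        lt = regularized_local_variance(lam2, tau2=0.3, c2=1e12)
        np.testing.assert_allclose(lt, lam2, rtol=1e-9)

    def test_saturated_regime_slab_variance(self):
        # tau^2 lam^2 >> c^2: lam_tilde^2 -> c^2 / tau^2, prior sd -> c
        tau2, c2 = 4.0, 2.0
        lt = regularized_local_variance(np.array([1e9]), tau2, c2)
        assert tau2 * lt[0] == pytest.approx(c2, rel=1e-6)

    def test_monotone_shrinkage_in_tau2(self):
        lam2, c2 = 1.7, 3.0
        taus = np.linspace(0.01, 50, 200)
        lt = regularized_local_variance(lam2, taus, c2)
        assert np.all(np.diff(lt) <= 1e-15)

    def test_recovers_signal_small_problem(self, toy_regression):
        X, y, _ = toy_regression(n=100, p=30, support=[0, 1], beta_vals=[3.0, -3.0],
                                 sigma=1.0, seed=13)
        res = fit_reg_horseshoe(X, y, McmcConfig(n_iter=2000, burn_in=500, seed=6), p0=2)
        pm = res.posterior_mean
        assert abs(pm[0]) > 2.0 and abs(pm[1]) > 2.0
        assert np.max(np.abs(pm[2:])) < 0.5

    def test_divergence_reported_with_iteration(self, rng):
        X = np.zeros((10, 3))
        y = np.full(10, np.nan)
        with pytest.raises(RuntimeError, match="iteration"):
            fit_horseshoe(X, y, McmcConfig(n_iter=50, burn_in=10, seed=0))
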