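"""Unit and property tests for the synthetic-data generator."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sparsebench.simdata import (
    SCENARIO1_MAGNITUDES,
    CoefficientSpec,
    SimConfig,
    calibrate_noise,
    generate,
    load_dataset,
    make_coefficients,
    make_design,
    make_nonlinear_dataset,
    make_response,
    nonlinear_mean,
    repaired_block_correlation,
    save_dataset,
    standardize,
)


class TestSimConfig:
    def test_requires_exactly_one_noise_spec(self):
        with pytest.raises(ValueError):
            SimConfig(snr=1.0, sigma_fixed=1.0)
        with pytest.raises(ValueError):
            SimConfig(snr=None, sigma_fixed=None)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"sparsity": 0.0},
            {"sparsity": 1.0},
            {"rho1": 1.0},
            {"rho3": -0.1},
            {"n_test": 0},
            {"design": "unknown"},
            {"error": "cauchy"},
            {"design": "nonlinear", "p": 5},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimConfig(**kwargs)


class TestMakeDesign:
    def test_continuous_columns_standard_normal(self, rng):
        cfg = SimConfig(n=2000, p=20)
        X = make_design(cfg, rng)
        assert X.shape == (2000, 20)
        # population mean 0, variance 1: 3-sigma Monte Carlo bands
        assert np.all(np.abs(X.mean(axis=0)) < 3 / np.sqrt(2000))
        assert np.all(np.abs(X.var(axis=0) - 1.0) < 3 * np.sqrt(2 / 2000))

    def test_binary_bernoulli_07(self, rng):
        cfg = SimConfig(n=10000, p=20, design="binary_indep")
        X = make_design(cfg, rng)
        assert set(np.unique(X)) <= {0.0, 1.0}
        se = np.sqrt(0.7 * 0.3 / 10000)
        assert np.all(np.abs(X.mean(axis=0) - 0.7) < 3 * se)

    def test_correlated_block_structure(self, rng):
        cfg = SimConfig(n=20000, p=50, design="correlated")
        support = np.arange(5)
        X = make_design(cfg, rng, support=support)
        corr = np.corrcoef(X, rowvar=False)
        se = 3 / np.sqrt(20000)
        # inactive/inactive pair ~ rho3 = 0.8
        assert abs(corr[10, 40] - 0.8) < 3 * se
        # active/active ~ rho1 = 0.3; active/inactive ~ rho2 = 0.5
        assert abs(corr[0, 1] - 0.3) < 5 * se
        assert abs(corr[0, 10] - 0.5) < 5 * se

    def test_correlated_requires_support(self, rng):
        with pytest.raises(ValueError, match="support"):
            make_design(SimConfig(design="correlated"), rng)

    @pytest.mark.parametrize("k1,k2", [(5, 45), (20, 30), (50, 50)])
    def test_pd_repair_small_blocks(self, k1, k2):
        sigma, dev = repaired_block_correlation(k1, k2, 0.3, 0.5, 0.8)
        assert np.linalg.eigvalsh(sigma)[0] > 0
        assert dev <= 0.05


class TestMakeCoefficients:
    def test_generic_counts_and_signs(self, rng):
        cfg = SimConfig(n=200, p=1000, sparsity=0.01)
        coef = make_coefficients(cfg, rng)
        assert coef.support.size == 10
        active = coef.beta[coef.support]
        assert np.sum(active > 0) == 5 and np.sum(active < 0) == 5
        assert np.all(np.abs(active) == 1.0)
        off = np.delete(coef.beta, coef.support)
        assert np.all(off == 0.0)

    def test_scenario1_cycled_magnitudes(self, rng):
        cfg = SimConfig(coef_regime="scenario1", snr=None, sigma_fixed=1.0)
        coef = make_coefficients(cfg, rng)
        assert coef.support.size == 10
        mags = np.abs(coef.beta[coef.support])
        assert sorted(mags) == sorted(SCENARIO1_MAGNITUDES)

    def test_scenario2_heterogeneous_magnitudes(self, rng):
        cfg = SimConfig(coef_regime="scenario2", snr=None, sigma_fixed=1.0)
        coef = make_coefficients(cfg, rng)
        mags = np.abs(coef.beta[coef.support])
        assert coef.support.size == 30
        assert np.all((mags >= 0.2) & (mags <= 0.7))
        signs = np.sign(coef.beta[coef.support])
        assert abs(signs.sum()) <= 1

    def test_single_active_feature(self, rng):
        coef = make_coefficients(SimConfig(n=50, p=100, sparsity=0.01), rng)
        assert coef.support.size == 1

    def test_empty_support_rejected(self, rng):
        with pytest.raises(ValueError, match="active"):
            make_coefficients(SimConfig(n=50, p=20, sparsity=0.01), rng)

    @given(st.integers(1, 40))
    def test_sign_balance_property(self, k):
        r = np.random.default_rng(k)
        cfg = SimConfig(n=200, p=400, sparsity=k / 400)
        coef = make_coefficients(cfg, r)
        signs = np.sign(coef.beta[coef.support])
        assert abs(int(signs.sum())) <= 1


class TestNoiseAndResponse:
    def test_calibration_arithmetic(self):
        # Var(X beta) = v  =>  sigma = sqrt(v / snr)
        x = np.linspace(-3, 3, 500)[:, None]
        v = np.var(x[:, 0], ddof=1)
        assert calibrate_noise(x, np.array([1.0]), snr=v) == pytest.approx(1.0)
        assert calibrate_noise(x, np.array([1.0]), snr=v / 2) == pytest.approx(np.sqrt(2))

    def test_calibration_rejects_constant_signal(self):
        X = np.ones((50, 1))
        with pytest.raises(ValueError, match="variance"):
            calibrate_noise(X, np.array([1.0]), snr=1.0)

    def test_null_signal_pure_noise(self, rng):
        X = rng.standard_normal((50000, 2))
        y = make_response(X, np.zeros(2), "gaussian", 1.0, np.random.default_rng(0))
        assert abs(y.mean()) < 3 / np.sqrt(50000)
        assert abs(y.var() - 1.0) < 3 * np.sqrt(2 / 50000)

    def test_fixed_seed_reproducible(self, rng):
        X = rng.standard_normal((20, 3))
        beta = np.array([1.0, 0.0, -1.0])
        y1 = make_response(X, beta, "t2", 2.0, np.random.default_rng(7))
        y2 = make_response(X, beta, "t2", 2.0, np.random.default_rng(7))
        np.testing.assert_array_equal(y1, y2)

    def test_gaussian_residual_variance(self, rng):
        X = rng.standard_normal((100000, 1))
        beta = np.array([2.0])
        sigma = 1.5
        y = make_response(X, beta, "gaussian", sigma, np.random.default_rng(3))
        ratio = np.var(y - X @ beta) / sigma**2
        assert abs(ratio - 1.0) < 3 * np.sqrt(2 / 100000)


class TestNonlinear:
    def test_closed_form_rows(self):
        row1 = np.array([[0.0, 0.0, 1.0, 1.0, 1.0, 0.0]])
        assert nonlinear_mean(row1)[0] == pytest.approx(1.0)
        row2 = np.array([[0.5, 1.0, 0.0, 1.0, 0.0, 2.0]])
        assert nonlinear_mean(row2)[0] == pytest.approx(3.0)

    def test_support_is_first_six(self):
        cfg = SimConfig(design="nonlinear", p=50, n=40)
        ds = make_nonlinear_dataset(cfg, np.random.default_rng(0))
        np.testing.assert_array_equal(ds.support, np.arange(6))
        assert np.all(ds.coef.beta == 0.0)


class TestGenerate:
    def test_default_benchmark_shapes(self):
        ds = generate(SimConfig(seed=1))
        assert ds.X_train.shape == (200, 1000)
        assert ds.X_test.shape == (50, 1000)
        assert ds.y_train.shape == (200,)
        assert ds.y_test.shape == (50,)

    def test_snr_calibration_exact_on_train(self):
        ds = generate(SimConfig(seed=2, snr=5.0))
        realized = np.var(ds.X_train @ ds.coef.beta, ddof=1) / ds.sigma**2
        assert realized == pytest.approx(5.0, abs=1e-10)

    def test_sigma_fixed_bypasses_calibration(self):
        ds = generate(SimConfig(seed=3, snr=None, sigma_fixed=1.0))
        assert ds.sigma == 1.0

    def test_same_seed_bitwise_identical(self):
        a = generate(SimConfig(seed=11))
        b = generate(SimConfig(seed=11))
        np.testing.assert_array_equal(a.X_train, b.X_train)
        np.testing.assert_array_equal(a.y_test, b.y_test)
        np.testing.assert_array_equal(a.support, b.support)

    def test_different_seeds_different_supports(self):
        supports = [tuple(generate(SimConfig(seed=s, p=500, n=50)).support) for s in range(5)]
        assert len(set(supports)) == 5

    def test_correlated_generate_runs(self):
        ds = generate(SimConfig(seed=4, design="correlated", p=100, n=50))
        assert ds.X_train.shape == (50, 100)

    def test_standardize_roundtrip(self):
        ds = generate(SimConfig(seed=5, p=50, n=60, sparsity=0.1))
        std = standardize(ds)
        assert np.allclose(std.X_train.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(std.X_train.var(axis=0), 1.0, atol=1e-12)
        assert std.y_train.mean() == pytest.approx(0.0, abs=1e-12)
        # same affine map applied to the test block
        np.testing.assert_allclose(
            std.X_test * std.x_scale + std.x_mean, ds.X_test, atol=1e-12
        )

    def test_serialization_roundtrip(self, tmp_path):
        ds = generate(SimConfig(seed=6, p=20, n=30, n_test=5, sparsity=0.2))
        save_dataset(ds, tmp_path)
        back = load_dataset(tmp_path)
        np.testing.assert_allclose(back.X_train, ds.X_train, atol=1e-12)
        np.testing.assert_allclose(back.y_test, ds.y_test, atol=1e-12)
        np.testing.assert_array_equal(back.support, ds.support)
        assert back.config == dataclasses.replace(ds.config)
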