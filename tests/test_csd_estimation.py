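"""MVAR fitting and analytic spectral conversion."""

import numpy as np
import pytest
from scipy import signal

from spdcm.csd_estimation import (
    MvarModel,
    bootstrap_csd_variance,
    estimate_csd,
    fit_mvar,
    mvar_csd,
    simulate_mvar,
)
from spdcm.spectral_forward import FrequencyGrid


def ar1_series(a, n, seed, sigma=1.0):
    rng = np.random.default_rng(seed)
    x = np.zeros(n)
    e = sigma * rng.standard_normal(n)
    for t in range(1, n):
        x[t] = a * x[t - 1] + e[t]
    return x


class TestFitMvar:
    def test_ar1_coefficient_recovery(self):
        n = 20000
        a = 0.5
        Y = np.column_stack([ar1_series(a, n, 0), ar1_series(a, n, 1)])
        m = fit_mvar(Y, order=1, dt=1.0)
        se = np.sqrt((1 - a**2) / n)  # asymptotic SE of the AR(1) estimate
        assert abs(m.coeffs[0, 0, 0] - a) < 3 * se
        assert abs(m.coeffs[0, 1, 1] - a) < 3 * se
        assert abs(m.coeffs[0, 0, 1]) < 3 * se

    def test_white_noise_has_null_coefficients(self):
        rng = np.random.default_rng(2)
        Y = rng.standard_normal((8000, 2))
        m = fit_mvar(Y, order=2, dt=1.0)
        assert np.max(np.abs(m.coeffs)) < 4 / np.sqrt(len(Y))
        np.testing.assert_allclose(m.sigma, np.cov(Y.T), atol=0.05)

    def test_default_order_is_eight(self):
        rng = np.random.default_rng(3)
        m = fit_mvar(rng.standard_normal((600, 2)), dt=2.0)
        assert m.order == 8
        assert m.coeffs.shape == (8, 2, 2)

    def test_insufficient_samples(self):
        with pytest.raises(ValueError, match="insufficient"):
            fit_mvar(np.zeros((10, 3)), order=8, dt=1.0)

    def test_channel_permutation_equivariance(self):
        rng = np.random.default_rng(4)
        Y = rng.standard_normal((2000, 3)).cumsum(axis=0) * 0.01
        Y += rng.standard_normal((2000, 3))
        perm = [2, 0, 1]
        m = fit_mvar(Y, order=2, dt=1.0)
        mp = fit_mvar(Y[:, perm], order=2, dt=1.0)
        np.testing.assert_allclose(
            mp.coeffs, m.coeffs[:, perm][:, :, perm], atol=1e-10
        )
        np.testing.assert_allclose(mp.sigma, m.sigma[np.ix_(perm, perm)], atol=1e-10)

    def test_scale_covariance(self):
        rng = np.random.default_rng(5)
        Y = rng.standard_normal((3000, 2))
        D = np.diag([2.0, 0.5])
        m = fit_mvar(Y, order=1, dt=1.0)
        ms = fit_mvar(Y @ D, order=1, dt=1.0)
        np.testing.assert_allclose(
            ms.coeffs[0], D @ m.coeffs[0] @ np.linalg.inv(D), atol=1e-10
        )
        np.testing.assert_allclose(ms.sigma, D @ m.sigma @ D, atol=1e-10)


class TestMvarCsd:
    def test_white_noise_is_flat_two_dt(self):
        m = MvarModel(coeffs=np.zeros((1, 2, 2)), sigma=np.eye(2), dt=1.0)
        grid = FrequencyGrid(np.array([0.05, 0.2, 0.4]))
        S = mvar_csd(m, grid).values
        np.testing.assert_allclose(
            S, 2.0 * np.eye(2)[None, :, :] * np.ones((3, 1, 1)), atol=1e-12
        )

    def test_scalar_ar1_closed_form(self):
        a, s2, dt = 0.6, 1.3, 2.0
        m = MvarModel(coeffs=np.full((1, 1, 1), a), sigma=np.array([[s2]]), dt=dt)
        grid = FrequencyGrid(np.linspace(0.01, 0.24, 12))
        S = mvar_csd(m, grid).values[:, 0, 0].real
        z = np.exp(-2j * np.pi * grid.frequencies * dt)
        expected = 2 * dt * s2 / np.abs(1 - a * z) ** 2
        np.testing.assert_allclose(S, expected, rtol=1e-12)

    def test_spectrum_integrates_to_process_variance(self):
        a, dt = 0.7, 1.0
        m = MvarModel(coeffs=np.full((1, 1, 1), a), sigma=np.eye(1), dt=dt)
        f = np.linspace(1e-4, 0.5 - 1e-9, 4000)
        S = mvar_csd(m, FrequencyGrid(f)).values[:, 0, 0].real
        var = np.trapezoid(S, f)
        assert var == pytest.approx(1.0 / (1 - a**2), rel=2e-3)

    def test_nonstationary_model_rejected(self):
        m = MvarModel(coeffs=np.full((1, 1, 1), 1.01), sigma=np.eye(1), dt=1.0)
        with pytest.raises(ValueError, match="nonstationary"):
            mvar_csd(m, FrequencyGrid(np.array([0.1])))

    def test_grid_beyond_nyquist_rejected(self):
        m = MvarModel(coeffs=np.zeros((1, 1, 1)), sigma=np.eye(1), dt=2.0)
        with pytest.raises(ValueError, match="Nyquist"):
            mvar_csd(m, FrequencyGrid(np.array([0.3])))

    def test_hermitian_psd_for_random_stationary_models(self):
        rng = np.random.default_rng(6)
        grid = FrequencyGrid(np.linspace(0.02, 0.45, 9))
        for _ in range(10):
            C = 0.3 * rng.standard_normal((2, 2, 2))
            L = rng.standard_normal((2, 2))
            m = MvarModel(coeffs=C, sigma=L @ L.T + 0.1 * np.eye(2), dt=1.0)
            if m.spectral_radius() >= 1:
                continue
            S = mvar_csd(m, grid)
            assert S.hermitian_error() < 1e-12
            assert S.min_eigenvalue() >= -1e-12


class TestEstimateCsd:
    def test_deterministic(self):
        rng = np.random.default_rng(7)
        Y = rng.standard_normal((512, 2))
        grid = FrequencyGrid(np.linspace(0.02, 0.2, 8))
        a = estimate_csd(Y, grid, dt=2.0).values
        b = estimate_csd(Y, grid, dt=2.0).values
        np.testing.assert_array_equal(a, b)

    def test_long_mvar_data_recovers_generating_spectrum(self):
        gen = MvarModel(
            coeffs=np.array([[[0.5, 0.2], [-0.1, 0.4]]]),
            sigma=np.array([[1.0, 0.3], [0.3, 0.8]]),
            dt=1.0,
        )
        Y = simulate_mvar(gen, 60000, seed=8)
        grid = FrequencyGrid(np.linspace(0.02, 0.45, 12))
        est = estimate_csd(Y, grid, order=4, dt=1.0).values
        ref = mvar_csd(gen, grid).values
        assert np.linalg.norm(est - ref) / np.linalg.norm(ref) < 0.05

    def test_matches_welch_periodogram(self):
        gen = MvarModel(
            coeffs=np.array([[[0.6, 0.0], [0.3, 0.5]]]),
            sigma=np.eye(2),
            dt=1.0,
        )
        Y = simulate_mvar(gen, 120000, seed=9)
        grid = FrequencyGrid(np.linspace(0.05, 0.4, 6))
        est = estimate_csd(Y, grid, order=4, dt=1.0).values
        f, P01 = signal.csd(Y[:, 0], Y[:, 1], fs=1.0, nperseg=2048)
        f, P00 = signal.welch(Y[:, 0], fs=1.0, nperseg=2048)
        w00 = np.interp(grid.frequencies, f, P00)
        w01r = np.interp(grid.frequencies, f, P01.real)
        # per-bin agreement within Welch's own sampling/resolution error,
        # plus a tighter check on the band-average level
        np.testing.assert_allclose(est[:, 0, 0].real, w00, rtol=0.35)
        np.testing.assert_allclose(est[:, 0, 1].real, w01r, rtol=0.35, atol=0.05)
        assert np.mean(est[:, 0, 0].real / w00) == pytest.approx(1.0, abs=0.08)

    def test_error_shrinks_with_sample_size(self):
        gen = MvarModel(
            coeffs=np.array([[[0.5, 0.25], [0.0, 0.45]]]),
            sigma=np.eye(2),
            dt=1.0,
        )
        grid = FrequencyGrid(np.linspace(0.02, 0.45, 10))
        ref = mvar_csd(gen, grid).values

        def err(n, seed):
            Y = simulate_mvar(gen, n, seed=seed)
            est = estimate_csd(Y, grid, order=1, dt=1.0).values
            return np.linalg.norm(est - ref) / np.linalg.norm(ref)

        small = np.mean([err(500, s) for s in range(5)])
        large = np.mean([err(20000, s + 10) for s in range(5)])
        assert large < small / 2

    def test_rejects_nonfinite(self):
        Y = np.zeros((100, 2))
        Y[3, 1] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            estimate_csd(Y, FrequencyGrid(np.array([0.1])), dt=1.0)


class TestBootstrapVariance:
    def test_seeded_and_positive(self):
        gen = MvarModel(
            coeffs=np.array([[[0.5, 0.0], [0.2, 0.4]]]), sigma=np.eye(2), dt=1.0
        )
        Y = simulate_mvar(gen, 1500, seed=10)
        grid = FrequencyGrid(np.linspace(0.05, 0.4, 6))
        v1 = bootstrap_csd_variance(Y, grid, order=2, dt=1.0, n_boot=8, seed=1)
        v2 = bootstrap_csd_variance(Y, grid, order=2, dt=1.0, n_boot=8, seed=1)
        np.testing.assert_array_equal(v1, v2)
        assert v1.shape == (2 * 6 * 4,)
        # structurally-zero features (diagonal imaginary parts) aside,
        # the estimator has positive sampling variance everywhere
        assert np.sort(v1)[len(v1) // 4] > 0
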