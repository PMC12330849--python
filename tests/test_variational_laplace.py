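"""Feature vectorization, free energy, and the Gauss-Newton update scheme."""

import numpy as np
import pytest
from scipy import stats

from spdcm.neural_models import assemble_circuit
from spdcm.spectral_forward import FrequencyGrid, NoiseSpectraParams, predict_csd
from spdcm.variational_laplace import (
    GaussianPrior,
    Hyperparameters,
    VLOptions,
    csd_parameter_jacobian,
    devectorize_csd,
    fit_features,
    free_energy,
    gauss_newton_step,
    vectorize_csd,
)


def three_region_model():
    A = np.array([[0.0, 0.4, 0.0], [-0.2, 0.0, -0.3], [0.0, 0.2, 0.0]])
    return assemble_circuit(["r1", "r2", "r3"], A)


class TestVectorization:
    def test_roundtrip_and_length(self):
        m = three_region_model()
        grid = FrequencyGrid.default_fmri(n=32)
        S = predict_csd(m, m.parameter_vector(), grid)
        vec = vectorize_csd(S)
        assert vec.shape == (2 * 32 * 9,)
        back = devectorize_csd(vec, grid, 3, labels=S.labels)
        np.testing.assert_array_equal(back.values, S.values)

    def test_hermitian_diagonal_contributes_zero_imaginary(self):
        m = three_region_model()
        grid = FrequencyGrid.default_fmri(n=4)
        S = predict_csd(m, m.parameter_vector(), grid)
        vec = vectorize_csd(S)
        imag = vec[4 * 9:].reshape(4, 3, 3)
        np.testing.assert_allclose(
            imag[:, range(3), range(3)], 0.0,
            atol=1e-14 * np.max(np.abs(vec)),
        )

    def test_devectorize_length_check(self):
        with pytest.raises(ValueError):
            devectorize_csd(np.zeros(10), FrequencyGrid(np.array([0.1])), 2)


class TestCsdParameterJacobian:
    def test_only_requested_columns(self):
        m = three_region_model()
        grid = FrequencyGrid.default_fmri(n=6)
        theta = m.parameter_vector()
        free = [m.index("a21"), m.index("alpha_meas")]
        J = csd_parameter_jacobian(m, theta, grid, free_indices=free)
        assert J.shape == (2 * 6 * 9, 2)

    def test_measurement_noise_column_closed_form(self):
        # d/d(alpha_meas) of exp(alpha_meas) f^-beta I is the term itself
        m = three_region_model()
        grid = FrequencyGrid.default_fmri(n=6)
        theta = m.parameter_vector()
        i = m.index("alpha_meas")
        J = csd_parameter_jacobian(m, theta, grid, free_indices=[i], steps=[1e-4])
        noise = NoiseSpectraParams.from_values(**m.noise_values(theta))
        term = noise.meas_psd(grid.frequencies)[:, None, None] * np.eye(3)
        expected = np.concatenate([term.ravel(), np.zeros(term.size)])
        np.testing.assert_allclose(J[:, 0], expected, rtol=1e-6, atol=1e-12)

    def test_central_differences_second_order(self):
        m = three_region_model()
        grid = FrequencyGrid.default_fmri(n=4)
        theta = m.parameter_vector()
        free = [m.index("a21")]
        J_h = csd_parameter_jacobian(m, theta, grid, free_indices=free, steps=[2e-2])
        J_h2 = csd_parameter_jacobian(m, theta, grid, free_indices=free, steps=[1e-2])
        J_ref = csd_parameter_jacobian(m, theta, grid, free_indices=free, steps=[1e-4])
        err_h = np.max(np.abs(J_h - J_ref))
        err_h2 = np.max(np.abs(J_h2 - J_ref))
        assert err_h2 < err_h / 3  # ~ O(h^2)

    def test_pluggable_backend_contract(self):
        m = three_region_model()
        grid = FrequencyGrid.default_fmri(n=4)
        theta = m.parameter_vector()
        free = [m.index("a12"), m.index("a21")]

        def forward_backend(fun, x0, steps):
            f0 = fun(x0)
            cols = []
            for i, h in enumerate(steps):
                e = np.zeros_like(x0)
                e[i] = h
                cols.append((fun(x0 + e) - f0) / h)
            return np.column_stack(cols)

        J_central = csd_parameter_jacobian(m, theta, grid, free_indices=free)
        J_plugged = csd_parameter_jacobian(
            m, theta, grid, free_indices=free, method=forward_backend
        )
        np.testing.assert_allclose(J_plugged, J_central, rtol=1e-2, atol=1e-8)


class TestFreeEnergy:
    def setup_problem(self):
        prior_mean = np.array([0.1, -0.2])
        prior_cov = np.diag([0.5, 0.8])
        hyper = Hyperparameters(mean=[0.0], var=[0.0], tunable=False)
        e = np.array([0.3, -0.1, 0.2])
        jac = np.array([[1.0, 0.0], [0.5, 1.0], [0.0, 1.0]])
        sigma_q = np.diag([0.1, 0.2])
        return e, jac, prior_mean, prior_cov, sigma_q, hyper

    def test_zero_parameter_kl_for_prior_posterior(self):
        e, jac, m_p, S_p, _, hyper = self.setup_problem()
        F_at_prior = free_energy(e, jac, m_p, S_p, m_p, S_p, hyper, np.zeros(1))
        F_shifted = free_energy(
            e, jac, m_p + 0.3, S_p, m_p, S_p, hyper, np.zeros(1)
        )
        # only the KL changes between these two; it is zero at the prior
        pi = np.ones(3)
        accuracy = (
            -0.5 * e @ (pi * e)
            - 0.5 * np.sum(S_p * (jac.T @ (pi[:, None] * jac)))
            + 0.5 * np.sum(np.log(pi))
            - 1.5 * np.log(2 * np.pi)
        )
        assert F_at_prior == pytest.approx(accuracy, rel=1e-12)
        assert F_shifted < F_at_prior

    def test_doubling_residual_decreases_f(self):
        e, jac, m_p, S_p, S_q, hyper = self.setup_problem()
        F1 = free_energy(e, jac, m_p, S_q, m_p, S_p, hyper, np.zeros(1))
        F2 = free_energy(2 * e, jac, m_p, S_q, m_p, S_p, hyper, np.zeros(1))
        assert F2 < F1


class TestUpdateMachinery:
    def test_infinite_damping_freezes_mean(self):
        jac = np.array([[1.0], [0.5]])
        step = gauss_newton_step(
            jac, np.array([1.0, 2.0]), np.ones(2), np.eye(1),
            np.zeros(1), np.zeros(1), damping=1e14,
        )
        assert abs(step[0]) < 1e-10

    def test_rejected_step_keeps_state_and_raises_damping(self):
        # a predictor that always returns non-finite values forces rejection
        prior = GaussianPrior.from_diagonal(["t"], [0.0], [1.0])
        hyper = Hyperparameters(mean=[0.0], var=[0.0], tunable=False)
        calls = {"n": 0}

        def predict(theta):
            calls["n"] += 1
            if calls["n"] <= 2:  # initial evaluation + Jacobian seeds
                return np.array([theta[0]])
            return np.array([np.nan])

        opts = VLOptions(max_iter=3)
        post = fit_features(predict, np.array([0.5]), prior, hyper, opts)
        rejected = [r for r in post.trace if not r.accepted]
        assert rejected
        assert np.all(np.diff([r.damping for r in rejected]) > 0)
        assert post.mean[0] == 0.0  # never moved


class TestConjugateGaussian:
    def test_scalar_posterior_and_evidence(self):
        m_p, v_p, v_e, y = 0.3, 0.5, 0.2, 1.1
        prior = GaussianPrior.from_diagonal(["theta"], [m_p], [v_p])
        hyper = Hyperparameters(mean=[np.log(1 / v_e)], var=[0.0], tunable=False)
        post = fit_features(lambda th: th.copy(), np.array([y]), prior, hyper)
        mean_true = (y / v_e + m_p / v_p) / (1 / v_e + 1 / v_p)
        var_true = 1 / (1 / v_e + 1 / v_p)
        log_ev = stats.norm.logpdf(y, loc=m_p, scale=np.sqrt(v_p + v_e))
        assert post["theta"] == pytest.approx(mean_true, abs=1e-8)
        assert post.variance("theta") == pytest.approx(var_true, abs=1e-8)
        assert post.free_energy == pytest.approx(log_ev, abs=1e-6)
        assert post.converged

    def test_multivariate_matches_analytic_posterior(self):
        rng = np.random.default_rng(12)
        d, n = 3, 7
        J = rng.standard_normal((n, d))
        v_e = 0.09
        prior = GaussianPrior.from_diagonal(
            [f"t{i}" for i in range(d)], np.zeros(d), np.full(d, 0.7)
        )
        y = J @ (0.5 * rng.standard_normal(d)) + 0.3 * rng.standard_normal(n)
        hyper = Hyperparameters(mean=[np.log(1 / v_e)], var=[0.0], tunable=False)
        post = fit_features(lambda th: J @ th, y, prior, hyper)
        S_q = np.linalg.inv(J.T @ J / v_e + np.eye(d) / 0.7)
        mu = S_q @ (J.T @ y / v_e)
        log_ev = stats.multivariate_normal.logpdf(
            y, mean=np.zeros(n), cov=J @ (0.7 * np.eye(d)) @ J.T + v_e * np.eye(n)
        )
        np.testing.assert_allclose(post.mean, mu, atol=1e-8)
        np.testing.assert_allclose(post.cov, S_q, atol=1e-8)
        assert post.free_energy == pytest.approx(log_ev, abs=1e-6)

    def test_zero_centered_prior_shrinks_toward_zero(self):
        # posterior mean lies between 0 and the maximum-likelihood estimate
        y = np.array([0.8])
        prior = GaussianPrior.from_diagonal(["t"], [0.0], [0.25])
        hyper = Hyperparameters(mean=[0.0], var=[0.0], tunable=False)
        post = fit_features(lambda th: th.copy(), y, prior, hyper)
        assert 0.0 < post["t"] < y[0]

    def test_estimated_precision_recovers_noise_level(self):
        rng = np.random.default_rng(13)
        n = 400
        sigma = 0.5
        y = sigma * rng.standard_normal(n)
        prior = GaussianPrior.from_diagonal(["t"], [0.0], [1e-8])
        hyper = Hyperparameters(mean=[0.0], var=[16.0], tunable=True)
        post = fit_features(lambda th: np.full(n, th[0]), y, prior, hyper)
        assert post.lambdas[0] == pytest.approx(np.log(1 / sigma**2), abs=0.3)

    def test_trace_monotone_and_serialization_roundtrip(self):
        prior = GaussianPrior.from_diagonal(["t"], [0.0], [0.5])
        hyper = Hyperparameters()
        y = np.array([0.9, 1.0, 1.1])
        post = fit_features(lambda th: np.repeat(th, 3), y, prior, hyper)
        F = post.accepted_free_energies()
        assert np.all(np.diff(F) >= -1e-9)
        from spdcm.variational_laplace import Posterior

        back = Posterior.from_dict(post.to_dict())
        np.testing.assert_array_equal(back.mean, post.mean)
        assert back.free_energy == post.free_energy
        assert back.to_dict()["schema_version"] == 1


class TestPriorContainer:
    def test_zero_variance_and_tunable_flags_define_free_subspace(self):
        prior = GaussianPrior.from_diagonal(
            ["a", "b", "c"], [0.0, 0.1, 0.2], [1.0, 0.0, 1.0]
        )
        assert prior.free_names() == ["a", "c"]
        prior.tunable[2] = False
        assert prior.free_names() == ["a"]

    def test_validation(self):
        with pytest.raises(ValueError):
            GaussianPrior.from_diagonal(["a"], [0.0, 1.0], [1.0])
        with pytest.raises(ValueError):
            GaussianPrior(names=["a"], mean=[0.0], cov=np.array([[-1.0]]))
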