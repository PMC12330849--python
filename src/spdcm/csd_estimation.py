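"""CSD estimation from time series via multivariate autoregressive fits.

Observed region time series are reduced to a cross-spectral density by
fitting a multivariate autoregressive (MVAR) model of fixed order 8 by
conditional maximum likelihood — equivalent to ordinary least squares on the
lagged regression, as provided by :class:`statsmodels` VAR — and converting
the fitted coefficients analytically to a spectrum:

    S(f) = 2*dt * H(f) Sigma H(f)^H,
    H(f) = (I - sum_k A_k exp(-2*pi*i*f*k*dt))^{-1}

under the one-sided, per-Hz convention shared with the forward model (the
integral of S over (0, Nyquist) is the process covariance).

Note this is deliberately a plain maximum-likelihood fit, not the Bayesian
AR fit used inside SPM (spm_mar.m); the two agree closely for the data sizes
of interest but not bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _signal
from statsmodels.tsa.vector_ar.var_model import VAR

from .spectral_forward import CrossSpectralDensity, FrequencyGrid

__all__ = [
    "MvarModel",
    "fit_mvar",
    "mvar_csd",
    "estimate_csd",
    "simulate_mvar",
    "bootstrap_csd_variance",
    "DEFAULT_MVAR_ORDER",
]

DEFAULT_MVAR_ORDER = 8


@dataclass
class MvarModel:
    """MVAR(p) model: lag coefficients, innovation covariance, sampling step.

    ``coeffs`` has shape (p, n_ch, n_ch) with ``Y_t = sum_k coeffs[k-1] @
    Y_{t-k} + e_t`` and ``sigma = Cov(e_t)`` (symmetric PSD); ``dt`` is the
    sampling interval in seconds.
    """

    coeffs: np.ndarray
    sigma: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        c = np.asarray(self.coeffs, dtype=float)
        if c.ndim == 2:
            c = c[None, :, :]
        if c.ndim != 3 or c.shape[1] != c.shape[2]:
            raise ValueError(f"lag coefficients must be (p, k, k), got {c.shape}")
        s = np.asarray(self.sigma, dtype=float)
        s = np.atleast_2d(s)
        if s.shape != (c.shape[1], c.shape[1]):
            raise ValueError("innovation covariance does not match channel count")
        if not np.allclose(s, s.T, atol=1e-10):
            raise ValueError("innovation covariance must be symmetric")
        if np.min(np.linalg.eigvalsh(0.5 * (s + s.T))) < -1e-10:
            raise ValueError("innovation covariance must be positive semidefinite")
        if self.dt <= 0:
            raise ValueError("sampling interval dt must be positive")
        self.coeffs = c
        self.sigma = 0.5 * (s + s.T)

    @property
    def order(self) -> int:
        return self.coeffs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.coeffs.shape[1]

    def companion(self) -> np.ndarray:
        p, k = self.order, self.n_channels
        C = np.zeros((p * k, p * k))
        C[:k, :] = np.concatenate(self.coeffs, axis=1)
        if p > 1:
            C[k:, : (p - 1) * k] = np.eye((p - 1) * k)
        return C

    def spectral_radius(self) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(self.companion()))))

    @property
    def nyquist(self) -> float:
        return 0.5 / self.dt


def fit_mvar(Y, order: int = DEFAULT_MVAR_ORDER, dt: float = 1.0) -> MvarModel:
    """Conditional maximum-likelihood MVAR fit (OLS on the lagged regression).

    Columns are mean-centered internally; ``sigma`` is the ML innovation
    covariance of the residuals (no degrees-of-freedom correction).
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2:
        raise ValueError(f"time series must be 2-D (n_time, n_ch), got {Y.ndim}-D")
    n_time, n_ch = Y.shape
    if order < 1:
        raise ValueError("MVAR order must be >= 1")
    if n_time <= order * n_ch + 1:
        raise ValueError(
            f"{n_time} samples are insufficient for an order-{order} fit of "
            f"{n_ch} channels (need > {order * n_ch + 1})"
        )
    Yc = Y - Y.mean(axis=0)
    try:
        res = VAR(Yc).fit(maxlags=order, trend="n")
    except np.linalg.LinAlgError as err:  # pragma: no cover - degenerate input
        raise ValueError(f"rank-deficient lagged regressor matrix: {err}") from err
    if res.k_ar != order:
        raise RuntimeError(f"VAR fit returned order {res.k_ar}, expected {order}")
    return MvarModel(coeffs=res.coefs.copy(), sigma=np.asarray(res.sigma_u_mle), dt=dt)


def mvar_csd(m: MvarModel, grid: FrequencyGrid) -> CrossSpectralDensity:
    """Analytic one-sided CSD of a stationary MVAR model on a frequency grid."""
    radius = m.spectral_radius()
    if radius >= 1.0:
        raise ValueError(
            f"MVAR model is nonstationary (companion spectral radius {radius:.4f})"
        )
    if grid.frequencies[-1] > m.nyquist * (1 + 1e-12):
        raise ValueError(
            f"grid extends to {grid.frequencies[-1]:.4g} Hz beyond the Nyquist "
            f"frequency {m.nyquist:.4g} Hz"
        )
    k = m.n_channels
    lags = np.arange(1, m.order + 1)
    z = np.exp(
        -2j * np.pi * grid.frequencies[:, None] * lags[None, :] * m.dt
    )  # (n_f, p)
    T = np.eye(k) - np.einsum("fp,pij->fij", z, m.coeffs.astype(complex))
    H = np.linalg.solve(T, np.broadcast_to(np.eye(k, dtype=complex), T.shape))
    S = 2.0 * m.dt * np.einsum("fij,jk,flk->fil", H, m.sigma, H.conj())
    return CrossSpectralDensity(values=S, grid=grid)


def estimate_csd(
    Y,
    grid: FrequencyGrid,
    order: int = DEFAULT_MVAR_ORDER,
    dt: float = 1.0,
    labels=None,
) -> CrossSpectralDensity:
    """Estimate the CSD of observed time series (detrend -> MVAR -> spectrum).

    Per-channel mean and linear trend are removed before the fit; no
    windowing or tapering is applied (the parametric estimate needs none).
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2:
        raise ValueError("time series must be 2-D (n_time, n_ch)")
    if not np.all(np.isfinite(Y)):
        raise ValueError("time series contains non-finite values")
    Yd = _signal.detrend(Y, axis=0, type="linear")
    model = fit_mvar(Yd, order=order, dt=dt)
    csd = mvar_csd(model, grid)
    if labels:
        csd.labels = list(labels)
    return csd


def simulate_mvar(m: MvarModel, n_time: int, seed=None, burn_in: int = 200) -> np.ndarray:
    """Draw a surrogate series from a fitted MVAR model (Gaussian innovations).

    Used for parametric-bootstrap calibration of the spectral estimator's
    sampling variability.
    """
    if m.spectral_radius() >= 1.0:
        raise ValueError("cannot simulate from a nonstationary MVAR model")
    rng = np.random.default_rng(seed)
    p, k = m.order, m.n_channels
    L = np.linalg.cholesky(m.sigma + 1e-12 * np.trace(m.sigma) / k * np.eye(k))
    total = n_time + burn_in
    X = np.zeros((total, k))
    eps = rng.standard_normal((total, k)) @ L.T
    for t in range(p, total):
        acc = eps[t].copy()
        for lag in range(p):
            acc += m.coeffs[lag] @ X[t - 1 - lag]
        X[t] = acc
    return X[burn_in:]


def bootstrap_csd_variance(
    Y,
    grid: FrequencyGrid,
    order: int = DEFAULT_MVAR_ORDER,
    dt: float = 1.0,
    n_boot: int = 32,
    seed=None,
) -> np.ndarray:
    """Per-feature sampling variance of the MVAR-based CSD estimator.

    Fits the MVAR model to ``Y``, simulates ``n_boot`` surrogate series of
    the same length, re-estimates their CSDs through the same pipeline and
    returns the variance of the stacked real/imaginary features
    (length 2 * n_freq * n_ch**2).  Seeded and deterministic.
    """
    from .variational_laplace import vectorize_csd  # avoid import cycle

    Y = np.asarray(Y, dtype=float)
    rng = np.random.default_rng(seed)
    base = fit_mvar(_signal.detrend(Y, axis=0, type="linear"), order=order, dt=dt)
    feats = np.array(
        [
            vectorize_csd(
                estimate_csd(simulate_mvar(base, Y.shape[0], seed=rng), grid,
                             order=order, dt=dt)
            )
            for _ in range(n_boot)
        ]
    )
    return np.var(feats, axis=0, ddof=1)
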