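"""Cross-spectral density prediction from the linearized generative model.

Around its resting fixed point the composed model is linearized to

    dx/dt = J x + B eps_f(t),     y = G x + eps_g(t)

and the stationary cross-spectral density of the observations is

    S_y(f) = K(f) S_ef(f) K(f)^H + S_eg(f),
    K(f) = G (2*pi*i*f*I - J)^{-1} B,

where ``K`` is the Fourier transform of the causal convolution kernel
``G exp(J tau) B`` and the state/measurement noise spectra follow power laws
in frequency.  All public interfaces use frequency ``f`` in Hz (one-sided,
per-Hz density convention); angular-frequency factors are internal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FrequencyGrid",
    "UnstableModelError",
    "LinearizedSystem",
    "NoiseSpectraParams",
    "CrossSpectralDensity",
    "linearize",
    "transfer_function",
    "noise_csd",
    "csd_from_linearized",
    "predict_csd",
]


class UnstableModelError(RuntimeError):
    """Raised when the model Jacobian is not Hurwitz-stable."""


@dataclass(frozen=True)
class FrequencyGrid:
    """Strictly positive, strictly increasing frequencies in Hz."""

    frequencies: np.ndarray

    def __post_init__(self) -> None:
        f = np.atleast_1d(np.asarray(self.frequencies, dtype=float))
        if f.size == 0:
            raise ValueError("frequency grid must be nonempty")
        if np.any(f <= 0):
            raise ValueError("frequencies must be strictly positive")
        if np.any(np.diff(f) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        object.__setattr__(self, "frequencies", f)

    @classmethod
    def default_fmri(
        cls,
        f_min: float = 1.0 / 128.0,
        f_max: float = 0.25,
        n: int = 32,
        nyquist: float | None = None,
    ) -> "FrequencyGrid":
        """Default resting-state band: n linearly spaced points on
        [1/128, 0.25] Hz, truncated at the data Nyquist frequency if given."""
        if nyquist is not None:
            f_max = min(f_max, nyquist)
        return cls(np.linspace(f_min, f_max, n))

    @property
    def n_freq(self) -> int:
        return self.frequencies.size

    def __len__(self) -> int:
        return self.n_freq


@dataclass
class LinearizedSystem:
    """Linearization (J, G, B) of a composed model at its expansion point.

    J: full-state Jacobian (s^-1); G: observation gradient
    (n_channels x n_states); B: state-noise input map
    (n_states x n_regions).
    """

    J: np.ndarray
    G: np.ndarray
    B: np.ndarray

    @property
    def n_states(self) -> int:
        return self.J.shape[0]

    @property
    def n_channels(self) -> int:
        return self.G.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.B.shape[1]

    def max_real_eigenvalue(self) -> float:
        return float(np.max(np.linalg.eigvals(self.J).real))

    def check_stable(self) -> None:
        eigs = np.linalg.eigvals(self.J)
        worst = eigs[np.argmax(eigs.real)]
        if worst.real >= 0:
            raise UnstableModelError(
                f"Jacobian is not Hurwitz-stable: eigenvalue {worst:.6g} "
                "has nonnegative real part"
            )


@dataclass(frozen=True)
class NoiseSpectraParams:
    """Power-law spectra of endogenous state noise and measurement noise.

    The state noise of region r has one-sided density
    ``(exp(alpha_global) + exp(alpha_region[r])) * f**(-beta_state)``:
    a global component shared by all regions plus a region-specific one, so
    diagonal entries may differ across regions.  Measurement noise has
    density ``exp(alpha_meas) * f**(-beta_meas)``, identical across
    channels.  By default a single exponent ``beta`` is shared by both.
    """

    alpha_global: float
    alpha_region: np.ndarray
    alpha_meas: float
    beta_state: float = 1.0
    beta_meas: float | None = None

    def __post_init__(self) -> None:
        ar = np.atleast_1d(np.asarray(self.alpha_region, dtype=float))
        object.__setattr__(self, "alpha_region", ar)
        if self.beta_meas is None:
            object.__setattr__(self, "beta_meas", float(self.beta_state))
        vals = [self.alpha_global, self.alpha_meas, self.beta_state, self.beta_meas]
        if not np.all(np.isfinite(ar)) or not np.all(np.isfinite(vals)):
            raise ValueError("noise spectrum parameters must be finite")

    @classmethod
    def from_values(cls, alpha_global, alpha_region, alpha_meas, beta):
        """Shared-exponent construction (the default configuration)."""
        return cls(
            alpha_global=float(alpha_global),
            alpha_region=alpha_region,
            alpha_meas=float(alpha_meas),
            beta_state=float(beta),
        )

    @property
    def n_regions(self) -> int:
        return self.alpha_region.size

    def state_psd(self, f) -> np.ndarray:
        """(n_freq, n_regions) one-sided state-noise density."""
        f = np.atleast_1d(np.asarray(f, dtype=float))
        amp = np.exp(self.alpha_global) + np.exp(self.alpha_region)
        return amp[None, :] * f[:, None] ** (-self.beta_state)

    def meas_psd(self, f) -> np.ndarray:
        """(n_freq,) one-sided measurement-noise density (all channels)."""
        f = np.atleast_1d(np.asarray(f, dtype=float))
        return np.exp(self.alpha_meas) * f ** (-self.beta_meas)


@dataclass
class CrossSpectralDensity:
    """Complex CSD over (frequency, channel, channel), Hermitian per frequency."""

    values: np.ndarray
    grid: FrequencyGrid
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=complex)
        if v.ndim != 3 or v.shape[1] != v.shape[2]:
            raise ValueError(f"CSD values must be (n_freq, n_ch, n_ch), got {v.shape}")
        if v.shape[0] != self.grid.n_freq:
            raise ValueError(
                f"{v.shape[0]} frequency slices for a grid of {self.grid.n_freq}"
            )
        self.values = v
        if not self.labels:
            self.labels = [f"ch{i + 1}" for i in range(v.shape[1])]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    @property
    def n_freq(self) -> int:
        return self.values.shape[0]

    def hermitian_error(self) -> float:
        """Largest absolute deviation from S(f) = S(f)^H."""
        return float(
            np.max(np.abs(self.values - self.values.conj().transpose(0, 2, 1)))
        )

    def min_eigenvalue(self) -> float:
        """Smallest eigenvalue of the Hermitian part over all frequencies."""
        h = 0.5 * (self.values + self.values.conj().transpose(0, 2, 1))
        return float(np.min(np.linalg.eigvalsh(h)))


def linearize(model, theta, perturb: float = 0.0, rng=None, fd_step: float = 1e-5):
    """Linearize a composed model at its expansion point.

    ``J = df/dx`` and ``G = dg/dx`` are computed by central finite
    differences of the (vectorized) flow and observation maps.  If
    ``perturb > 0``, i.i.d. Gaussian offsets of that scale are added to the
    expansion point — an option to move off degenerate (repeated-eigenvalue)
    expansion points when a differentiation backend requires it.  Stability
    is verified; an :class:`UnstableModelError` names the offending
    eigenvalue.
    """
    x0 = model.expansion_point()
    if perturb:
        rng = np.random.default_rng(rng)
        x0 = x0 + perturb * rng.standard_normal(x0.shape)
    n = x0.size
    steps = fd_step * np.eye(n)
    fp = model.flow(x0 + steps, theta)
    fm = model.flow(x0 - steps, theta)
    J = (fp - fm).T / (2.0 * fd_step)
    gp = model.observe(x0 + steps, theta)
    gm = model.observe(x0 - steps, theta)
    # observe() maps (n_points, n_states) -> (n_points, n_channels); the
    # gradient w.r.t. states is the transpose of the difference quotient.
    G = (gp - gm).T / (2.0 * fd_step)
    lin = LinearizedSystem(J=J, G=G, B=model.noise_input_map())
    lin.check_stable()
    return lin


def transfer_function(lin: LinearizedSystem, grid: FrequencyGrid) -> np.ndarray:
    """Kernel Fourier transform K(f) = G (2*pi*i*f*I - J)^{-1} B.

    Returns a complex (n_freq, n_channels, n_inputs) array.
    """
    lin.check_stable()
    w = 2j * np.pi * grid.frequencies
    eye = np.eye(lin.n_states)
    M = w[:, None, None] * eye - lin.J[None, :, :]
    X = np.linalg.solve(M, np.broadcast_to(lin.B, (grid.n_freq, *lin.B.shape)))
    return np.einsum("cs,fsr->fcr", lin.G, X)


def noise_csd(
    p: NoiseSpectraParams, grid: FrequencyGrid, n_regions: int, n_channels: int
):
    """Diagonals of the state- and measurement-noise CSDs on the grid.

    Returns ``(S_ef, S_eg)`` with shapes (n_freq, n_regions) and
    (n_freq, n_channels); off-diagonal terms vanish by the uncorrelated-noise
    assumption.
    """
    if p.n_regions != n_regions:
        raise ValueError(
            f"noise parameters describe {p.n_regions} regions, expected {n_regions}"
        )
    S_ef = p.state_psd(grid.frequencies)
    S_eg = np.repeat(p.meas_psd(grid.frequencies)[:, None], n_channels, axis=1)
    return S_ef, S_eg


def csd_from_linearized(
    lin: LinearizedSystem,
    noise: NoiseSpectraParams,
    grid: FrequencyGrid,
    labels=None,
) -> CrossSpectralDensity:
    """Predicted observation CSD for an explicit linearized system."""
    K = transfer_function(lin, grid)
    S_ef, S_eg = noise_csd(noise, grid, lin.n_inputs, lin.n_channels)
    S = np.einsum("fcr,fr,fdr->fcd", K, S_ef, K.conj())
    S = S + S_eg[:, :, None] * np.eye(lin.n_channels)
    return CrossSpectralDensity(values=S, grid=grid, labels=list(labels or []))


def predict_csd(
    model, theta, grid: FrequencyGrid, perturb: float = 0.0, rng=None
) -> CrossSpectralDensity:
    """Predicted BOLD cross-spectral density of a composed model at theta."""
    lin = linearize(model, theta, perturb=perturb, rng=rng)
    noise = NoiseSpectraParams.from_values(**model.noise_values(theta))
    return csd_from_linearized(lin, noise, grid, labels=model.labels)
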