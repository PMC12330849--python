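"""Linear neural-mass regions and their assembly into a circuit.

A region's neuronal activity is a single scalar ``x_n`` whose flow is exactly
linear in the full neuronal state vector: ``x_n' = (A x_n)_region``, where the
effective-connectivity matrix ``A`` collects directed coupling rates in Hz.
We follow the (target-row, source-column) convention: ``A[y-1, x-1]`` holds
``a_xy``, the influence exerted by region ``x`` onto region ``y``.

Self connections (the diagonal) are parameterized as ``-0.5 * exp(a_xx)`` so
that the prior mean ``a_xx = 0`` yields a stabilizing -0.5 Hz leak and any
real-valued parameter keeps the diagonal negative.

A :class:`ComposedModel` stacks, per region, the neuronal state and the four
balloon-model states.  Blood flow, volume and deoxyhemoglobin are propagated
in log space (state layout per region: ``[x_n, s, ln u, ln v, ln q]``) so
positivity is structural and the resting fixed point is the zero vector —
the expansion point of the spectral forward model.  The observation is the
BOLD signal in percent signal change.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import hemodynamics as hemo

__all__ = [
    "ModelSpecError",
    "LinearNeuralMass",
    "EffectiveConnectivity",
    "ComposedModel",
    "linear_flow",
    "assemble_circuit",
    "pack_parameters",
    "unpack_parameters",
    "STATES_PER_REGION",
    "BOLD_SIGNAL_SCALE",
]

#: states per region for the fMRI model: x_n, s, ln u, ln v, ln q
STATES_PER_REGION = 5

#: the observation is reported in percent signal change (100 * lambda)
BOLD_SIGNAL_SCALE = 100.0

#: self-connection strength at prior mean: diagonal = -SELF_SCALE * exp(a_xx)
SELF_SCALE = 0.5


class ModelSpecError(ValueError):
    """Raised for inconsistent model specifications (sizes, labels)."""


@dataclass(frozen=True)
class LinearNeuralMass:
    """A single-region linear neural mass (one scalar activity state)."""

    label: str

    n_states: int = field(default=1, init=False, repr=False)


@dataclass(frozen=True)
class EffectiveConnectivity:
    """Directed coupling rates between regions (Hz).

    ``matrix[y, x]`` (0-based) holds ``a_{x+1, y+1}``: the influence of
    region ``x+1`` onto region ``y+1``.  The diagonal stores the
    self-connection *parameters* ``a_xx`` (the effective diagonal rate is
    ``-0.5 * exp(a_xx)``, applied by :class:`ComposedModel`).
    """

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ModelSpecError(
                f"connectivity must be square, got shape {m.shape}"
            )
        object.__setattr__(self, "matrix", m)

    @property
    def n_regions(self) -> int:
        return self.matrix.shape[0]


def linear_flow(A, x) -> np.ndarray:
    """Neuronal flow A @ x under the (target-row, source-column) convention.

    ``A`` may be an :class:`EffectiveConnectivity` or a square array.
    """
    if isinstance(A, EffectiveConnectivity):
        A = A.matrix
    A = np.asarray(A, dtype=float)
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != A.shape[1]:
        raise ModelSpecError(
            f"state dimension {x.shape[-1]} does not match "
            f"{A.shape[1]} regions"
        )
    return x @ A.T


def _connection_name(source: int, target: int, n: int) -> str:
    """Canonical parameter name for a_xy (1-based source x, target y)."""
    if n <= 9:
        return f"a{source}{target}"
    return f"a_{source}_{target}"


@dataclass
class ComposedModel:
    """Assembled generative model: linear circuit + balloon/BOLD per region.

    Parameters (canonical packing order):

    1. connections ``a_xy`` in row-major matrix order (target y outer,
       source x inner); the diagonal entries are self-connection parameters;
    2. ``transit{r}``: log-scaling of region r's transit time,
       ``tau_eff = tau_default * exp(transit)``;
    3. noise-spectrum parameters ``alpha_global``, ``alpha_region{r}``,
       ``alpha_meas`` (log-amplitudes) and ``beta`` (power-law exponent).

    Use :func:`pack_parameters` / :func:`unpack_parameters` to move between
    named assignments and the flat vector.
    """

    regions: list[LinearNeuralMass]
    connectivity: EffectiveConnectivity
    hemo_params: list[hemo.HemodynamicParams]
    bold_params: hemo.BoldParams
    noise_defaults: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.regions)
        if n < 1:
            raise ModelSpecError("need at least one region")
        labels = [r.label for r in self.regions]
        if len(set(labels)) != n:
            raise ModelSpecError(f"duplicate region labels in {labels}")
        if self.connectivity.n_regions != n:
            raise ModelSpecError(
                f"connectivity is {self.connectivity.n_regions}x"
                f"{self.connectivity.n_regions} but there are {n} regions"
            )
        if len(self.hemo_params) != n:
            raise ModelSpecError(
                f"{len(self.hemo_params)} hemodynamic parameter sets for "
                f"{n} regions"
            )
        names: list[str] = []
        defaults: list[float] = []
        A = self.connectivity.matrix
        for y in range(1, n + 1):  # target (row)
            for x in range(1, n + 1):  # source (column)
                names.append(_connection_name(x, y, n))
                defaults.append(A[y - 1, x - 1])
        for r in range(1, n + 1):
            names.append(f"transit{r}")
            defaults.append(0.0)
        noise_names = (
            ["alpha_global"]
            + [f"alpha_region{r}" for r in range(1, n + 1)]
            + ["alpha_meas", "beta"]
        )
        noise_base = {name: 0.0 for name in noise_names}
        noise_base["beta"] = 1.0
        unknown = set(self.noise_defaults) - set(noise_base)
        if unknown:
            raise ModelSpecError(f"unknown noise parameters: {sorted(unknown)}")
        noise_base.update(self.noise_defaults)
        names.extend(noise_names)
        defaults.extend(noise_base[name] for name in noise_names)
        self._names = names
        self._defaults = np.array(defaults, dtype=float)
        self._index = {name: i for i, name in enumerate(names)}
        # per-region parameter arrays for vectorized flow evaluation
        self._kappa = np.array([p.kappa for p in self.hemo_params])
        self._gamma = np.array([p.gamma for p in self.hemo_params])
        self._tau0 = np.array([p.tau for p in self.hemo_params])
        self._alpha = np.array([p.alpha for p in self.hemo_params])
        self._E0 = np.array([p.E0 for p in self.hemo_params])
        self._conn_slice = slice(0, n * n)
        self._transit_slice = slice(n * n, n * n + n)

    # -- structure ---------------------------------------------------------

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def n_states(self) -> int:
        return STATES_PER_REGION * self.n_regions

    @property
    def labels(self) -> list[str]:
        return [r.label for r in self.regions]

    @property
    def param_names(self) -> list[str]:
        return list(self._names)

    @property
    def n_params(self) -> int:
        return len(self._names)

    def index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise KeyError(f"unknown parameter {name!r}") from None

    def parameter_vector(self) -> np.ndarray:
        """Default (assembly-time) parameter vector."""
        return self._defaults.copy()

    def expansion_point(self) -> np.ndarray:
        """The resting fixed point: the zero vector in log coordinates."""
        return np.zeros(self.n_states)

    def noise_input_map(self) -> np.ndarray:
        """State-noise input matrix B (n_states x n_regions).

        Endogenous fluctuations drive the neuronal states only.
        """
        B = np.zeros((self.n_states, self.n_regions))
        for r in range(self.n_regions):
            B[STATES_PER_REGION * r, r] = 1.0
        return B

    # -- parameter handling ------------------------------------------------

    def _check_theta(self, theta) -> np.ndarray:
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.n_params,):
            raise ValueError(
                f"parameter vector has shape {theta.shape}, "
                f"expected ({self.n_params},)"
            )
        return theta

    def connectivity_matrix(self, theta) -> np.ndarray:
        """Effective connectivity A(theta) with -0.5*exp(a_xx) diagonal."""
        theta = self._check_theta(theta)
        n = self.n_regions
        A = theta[self._conn_slice].reshape(n, n).copy()
        diag = A.diagonal().copy()
        np.fill_diagonal(A, -SELF_SCALE * np.exp(diag))
        return A

    def transit_times(self, theta) -> np.ndarray:
        """Effective transit times tau_default * exp(transit_r)."""
        theta = self._check_theta(theta)
        return self._tau0 * np.exp(theta[self._transit_slice])

    def noise_values(self, theta) -> dict[str, object]:
        """Noise-spectrum parameters as keyword arguments."""
        theta = self._check_theta(theta)
        n = self.n_regions
        return {
            "alpha_global": float(theta[self._index["alpha_global"]]),
            "alpha_region": np.array(
                [theta[self._index[f"alpha_region{r}"]] for r in range(1, n + 1)]
            ),
            "alpha_meas": float(theta[self._index["alpha_meas"]]),
            "beta": float(theta[self._index["beta"]]),
        }

    # -- dynamics ----------------------------------------------------------

    def flow(self, x, theta) -> np.ndarray:
        """Full deterministic flow, vectorized over leading batch axes.

        ``x`` has shape (..., n_states) with the per-region layout
        ``[x_n, s, ln u, ln v, ln q]``.
        """
        theta = self._check_theta(theta)
        x = np.asarray(x, dtype=float)
        if x.shape[-1] != self.n_states:
            raise ValueError(
                f"state has dimension {x.shape[-1]}, expected {self.n_states}"
            )
        A = self.connectivity_matrix(theta)
        tau = self.transit_times(theta)
        xn = x[..., 0::STATES_PER_REGION]
        s = x[..., 1::STATES_PER_REGION]
        u = np.exp(x[..., 2::STATES_PER_REGION])
        v = np.exp(x[..., 3::STATES_PER_REGION])
        q = np.exp(x[..., 4::STATES_PER_REGION])
        outflow = v ** (1.0 / self._alpha)  # v**(1/alpha)
        E = 1.0 - (1.0 - self._E0) ** (1.0 / u)
        dxn = xn @ A.T
        ds = xn - self._kappa * s - self._gamma * (u - 1.0)
        dlu = s / u
        dlv = (u - outflow) / (tau * v)
        dlq = (u * E / (self._E0 * q) - outflow / v) / tau
        out = np.empty_like(x)
        out[..., 0::STATES_PER_REGION] = dxn
        out[..., 1::STATES_PER_REGION] = ds
        out[..., 2::STATES_PER_REGION] = dlu
        out[..., 3::STATES_PER_REGION] = dlv
        out[..., 4::STATES_PER_REGION] = dlq
        return out

    def observe(self, x, theta) -> np.ndarray:
        """BOLD observation (percent signal change), one channel per region."""
        self._check_theta(theta)
        x = np.asarray(x, dtype=float)
        v = np.exp(x[..., 3::STATES_PER_REGION])
        q = np.exp(x[..., 4::STATES_PER_REGION])
        out = np.empty_like(v)
        for r in range(self.n_regions):
            out[..., r] = BOLD_SIGNAL_SCALE * hemo.bold_signal(
                q[..., r], v[..., r], self.bold_params, E0=self._E0[r]
            )
        return out

    def permuted(self, order: Sequence[int]) -> "ComposedModel":
        """Model with regions reordered (used for equivariance checks)."""
        order = list(order)
        if sorted(order) != list(range(self.n_regions)):
            raise ModelSpecError(f"invalid permutation {order}")
        A = self.connectivity.matrix[np.ix_(order, order)]
        return ComposedModel(
            regions=[self.regions[i] for i in order],
            connectivity=EffectiveConnectivity(A),
            hemo_params=[self.hemo_params[i] for i in order],
            bold_params=self.bold_params,
            noise_defaults=dict(self.noise_defaults),
        )


def assemble_circuit(
    regions: Sequence[LinearNeuralMass | str],
    connectivity,
    hemodynamic_params=None,
    bold_params: hemo.BoldParams | None = None,
    noise_defaults: Mapping[str, float] | None = None,
) -> ComposedModel:
    """Compose region models into a full generative circuit.

    ``regions`` may be labels or :class:`LinearNeuralMass` instances;
    ``hemodynamic_params`` a single :class:`hemo.HemodynamicParams` shared by
    all regions or one per region.
    """
    region_objs = [
        r if isinstance(r, LinearNeuralMass) else LinearNeuralMass(str(r))
        for r in regions
    ]
    if not isinstance(connectivity, EffectiveConnectivity):
        connectivity = EffectiveConnectivity(np.asarray(connectivity, dtype=float))
    n = len(region_objs)
    if hemodynamic_params is None:
        hemodynamic_params = hemo.HemodynamicParams()
    if isinstance(hemodynamic_params, hemo.HemodynamicParams):
        hemo_list = [hemodynamic_params] * n
    else:
        hemo_list = list(hemodynamic_params)
    return ComposedModel(
        regions=region_objs,
        connectivity=connectivity,
        hemo_params=hemo_list,
        bold_params=bold_params if bold_params is not None else hemo.BoldParams(),
        noise_defaults=dict(noise_defaults or {}),
    )


def pack_parameters(model: ComposedModel, values: Mapping[str, float]) -> np.ndarray:
    """Flat parameter vector in canonical order, defaults overridden by ``values``."""
    theta = model.parameter_vector()
    for name, value in values.items():
        theta[model.index(name)] = value
    return theta


def unpack_parameters(model: ComposedModel, theta) -> dict[str, float]:
    """Named parameter assignment from a flat vector (inverse of pack)."""
    theta = model._check_theta(theta)
    return {name: float(theta[i]) for i, name in enumerate(model.param_names)}
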