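"""Balloon-model hemodynamics and the BOLD observation equation.

The balloon model maps neuronal activity ``x_n`` to a vasodilatory signal
``s``, normalized cerebral blood flow ``u``, venous blood volume ``v`` and
deoxyhemoglobin content ``q`` (all normalized to 1 at rest)::

    s' = x_n - kappa*s - gamma*(u - 1)
    u' = s
    tau * v' = u - v**(1/alpha)
    tau * q' = u*E(u, E0)/E0 - v**(1/alpha) * q/v

with the oxygen extraction fraction ``E(u, E0) = 1 - (1 - E0)**(1/u)``.
The BOLD signal change is

    lambda(q, v) = V0 * [k1*(1 - q) + k2*(1 - q/v) + k3*(1 - v)]

where the coefficients depend on acquisition parameters (echo time, field
strength) through ``k1 = 4.3*theta0*E0*TE``, ``k2 = epsilon*r0*E0*TE`` and
``k3 = 1 - epsilon``.

The resting state ``(s, u, v, q) = (0, 1, 1, 1)`` with ``x_n = 0`` is an
exact fixed point and the expansion point of the spectral forward model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "HemodynamicState",
    "HemodynamicParams",
    "BoldParams",
    "FIELD_STRENGTH_PRESETS",
    "bold_params_for_field",
    "oxygen_extraction",
    "hemodynamic_flow",
    "bold_coefficients",
    "bold_signal",
]


@dataclass(frozen=True)
class HemodynamicState:
    """Hemodynamic state of a single region.

    ``u``, ``v`` and ``q`` are normalized to their resting value 1 and must
    stay positive; ``s`` is the (signed) vasodilatory signal.
    """

    s: float = 0.0
    u: float = 1.0
    v: float = 1.0
    q: float = 1.0

    def __post_init__(self) -> None:
        if self.u <= 0 or self.v <= 0 or self.q <= 0:
            raise ValueError(
                f"flow/volume/deoxyhemoglobin must be positive, got "
                f"u={self.u}, v={self.v}, q={self.q}"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.s, self.u, self.v, self.q], dtype=float)


@dataclass(frozen=True)
class HemodynamicParams:
    """Balloon-model rate constants (units: kappa, gamma in s^-1; tau in s).

    Defaults are standard resting-state balloon-model values; ``tau`` is the
    mean transit time at rest, ``alpha`` Grubb's vessel stiffness exponent
    and ``E0`` the resting oxygen extraction fraction.
    """

    kappa: float = 0.64
    gamma: float = 0.32
    tau: float = 2.0
    alpha: float = 0.32
    E0: float = 0.4

    def __post_init__(self) -> None:
        if min(self.kappa, self.gamma, self.tau) <= 0:
            raise ValueError("kappa, gamma and tau must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if not 0 < self.E0 < 1:
            raise ValueError(f"E0 must lie in (0, 1), got {self.E0}")


#: Field-strength presets for (theta0, r0, epsilon_ratio).  These are
#: synthetic, literature-derived placeholder values (theta0 scales roughly
#: linearly with B0; r0 grows super-linearly; the intravascular fraction
#: epsilon drops at high field).  They are configuration, not authoritative
#: constants, and should be overridden when calibrated values are available.
FIELD_STRENGTH_PRESETS: dict[str, dict[str, float]] = {
    "1.5T": {"theta0": 40.3, "r0": 25.0, "epsilon_ratio": 1.0},
    "3T": {"theta0": 80.6, "r0": 110.0, "epsilon_ratio": 0.47},
    "7T": {"theta0": 188.1, "r0": 325.0, "epsilon_ratio": 0.13},
}


@dataclass(frozen=True)
class BoldParams:
    """Parameters of the BOLD observation equation.

    ``V0`` resting venous volume fraction, ``theta0`` frequency offset of
    fully deoxygenated blood (s^-1), ``r0`` intravascular relaxation slope
    (s^-1), ``epsilon_ratio`` intra-/extravascular signal ratio at rest and
    ``TE`` the echo time (s).  Defaults correspond to the classic 1.5T
    calibration with TE = 40 ms.
    """

    V0: float = 0.04
    theta0: float = 40.3
    r0: float = 25.0
    epsilon_ratio: float = 1.0
    TE: float = 0.04
    field_strength: str | None = None

    def __post_init__(self) -> None:
        if self.TE <= 0:
            raise ValueError(f"echo time TE must be positive, got {self.TE}")
        if self.V0 <= 0:
            raise ValueError(f"V0 must be positive, got {self.V0}")


def bold_params_for_field(
    field_strength: str, TE: float = 0.04, V0: float = 0.04
) -> BoldParams:
    """Build :class:`BoldParams` from a field-strength preset label."""
    try:
        preset = FIELD_STRENGTH_PRESETS[field_strength]
    except KeyError:
        raise KeyError(
            f"unknown field strength {field_strength!r}; "
            f"available: {sorted(FIELD_STRENGTH_PRESETS)}"
        ) from None
    return BoldParams(V0=V0, TE=TE, field_strength=field_strength, **preset)


def oxygen_extraction(u, E0):
    """Oxygen extraction fraction E(u, E0) = 1 - (1 - E0)**(1/u).

    Vectorized in ``u``; E0 may be a scalar or an array broadcastable
    against ``u``.  E -> E0 at rest (u = 1), E -> 1 as u -> 0+ and E -> 0 as
    u -> inf.
    """
    u = np.asarray(u, dtype=float)
    if np.any(u <= 0):
        raise ValueError("normalized blood flow u must be positive")
    E0 = np.asarray(E0, dtype=float)
    if np.any((E0 <= 0) | (E0 >= 1)):
        raise ValueError("E0 must lie in (0, 1)")
    out = 1.0 - (1.0 - E0) ** (1.0 / u)
    return float(out) if out.ndim == 0 else out


def hemodynamic_flow(state, x_n: float, p: HemodynamicParams) -> np.ndarray:
    """Time derivative (ds, du, dv, dq) of the balloon model.

    ``state`` may be a :class:`HemodynamicState` or a length-4 array
    ``(s, u, v, q)`` in natural (not log) coordinates.
    """
    if isinstance(state, HemodynamicState):
        s, u, v, q = state.s, state.u, state.v, state.q
    else:
        s, u, v, q = np.asarray(state, dtype=float)
    if u <= 0 or v <= 0 or q <= 0:
        raise ValueError("u, v and q must be positive")
    E = oxygen_extraction(u, p.E0)
    outflow = v ** (1.0 / p.alpha)
    ds = x_n - p.kappa * s - p.gamma * (u - 1.0)
    du = s
    dv = (u - outflow) / p.tau
    dq = (u * E / p.E0 - outflow * q / v) / p.tau
    return np.array([ds, du, dv, dq])


def bold_coefficients(b: BoldParams, E0: float = 0.4) -> tuple[float, float, float]:
    """BOLD signal coefficients (k1, k2, k3).

    k1 = 4.3*theta0*E0*TE, k2 = epsilon*r0*E0*TE, k3 = 1 - epsilon.  The
    resting oxygen extraction fraction ``E0`` belongs to the hemodynamics
    (see :class:`HemodynamicParams`) and is passed explicitly so that the
    observation coefficients stay consistent with the region's balloon
    parameters.
    """
    if not 0 < E0 < 1:
        raise ValueError(f"E0 must lie in (0, 1), got {E0}")
    k1 = 4.3 * b.theta0 * E0 * b.TE
    k2 = b.epsilon_ratio * b.r0 * E0 * b.TE
    k3 = 1.0 - b.epsilon_ratio
    return k1, k2, k3


def bold_signal(q, v, b: BoldParams, E0: float = 0.4):
    """Fractional BOLD signal change lambda(q, v).

    lambda = V0*[k1*(1 - q) + k2*(1 - q/v) + k3*(1 - v)].  Vectorized in
    ``q`` and ``v``; zero at the resting point (q, v) = (1, 1).
    """
    q = np.asarray(q, dtype=float)
    v = np.asarray(v, dtype=float)
    if np.any(v <= 0) or np.any(q <= 0):
        raise ValueError("v and q must be positive")
    k1, k2, k3 = bold_coefficients(b, E0=E0)
    out = b.V0 * (k1 * (1.0 - q) + k2 * (1.0 - q / v) + k3 * (1.0 - v))
    return float(out) if out.ndim == 0 else out
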