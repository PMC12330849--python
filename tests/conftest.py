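"""Shared fixtures: small models, and the seeded recovery/comparison battery.

The battery (10 seeds of the default three-region scenario, each inverted
under the ground-truth prior structure, the four single-connection
removals, and the fully connected over-complex structure) is expensive, so
it is computed once per session and shared by the recovery, model-selection
and free-energy-monotonicity tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from spdcm.csd_estimation import estimate_csd
from spdcm.model_comparison import exclude_parameter
from spdcm.pipeline import calibrated_hyperparameters
from spdcm.synthetic_data import default_scenario
from spdcm.variational_laplace import invert

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

TRUE_CONNECTIONS = {"a12": -0.2, "a21": 0.4, "a32": -0.3, "a23": 0.2}
BATTERY_SEEDS = tuple(range(1, 11))


@dataclass
class BatteryRun:
    seed: int
    scenario: object
    posterior: object            # ground-truth prior structure
    alternatives: dict           # label -> Posterior (removals + over-complex)


def _include_connection(prior, name, var=1.0 / 128.0):
    out = prior.copy()
    i = out.index(name)
    out.mean[i] = 0.0
    out.cov[i, i] = var
    return out


@pytest.fixture(scope="session")
def battery():
    runs = []
    for seed in BATTERY_SEEDS:
        sc = default_scenario(seed=seed)
        csd = estimate_csd(sc.data, sc.grid, dt=sc.tr, labels=sc.labels)
        hyper = calibrated_hyperparameters(csd, sc.data, sc.tr, seed=seed)
        post = invert(csd, sc.model, sc.prior, hyper=hyper)
        alts = {}
        for name in TRUE_CONNECTIONS:
            alts["minus_" + name] = invert(
                csd, sc.model, exclude_parameter(sc.prior, name), hyper=hyper
            )
        full_prior = _include_connection(
            _include_connection(sc.prior, "a13"), "a31"
        )
        alts["over_complex"] = invert(csd, sc.model, full_prior, hyper=hyper)
        runs.append(
            BatteryRun(seed=seed, scenario=sc, posterior=post, alternatives=alts)
        )
    return runs


@pytest.fixture(scope="session")
def small_scenario():
    """A short, cheap scenario for structural (non-statistical) checks."""
    return default_scenario(seed=7, n_volumes=256)
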