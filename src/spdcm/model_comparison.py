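"""Prior surgery and free-energy-based model comparison.

A model space is defined by editing the prior: *excluding* a parameter sets
its prior mean and variance to zero, fixing it at 0 during inversion
(removing the connection from the model); clearing the *tunable* flag
freezes a parameter at its — possibly nonzero — prior mean, representing a
fixed effective connection.  Competing models fitted to the *same* data are
then ranked by their free energy, an approximation to the log model
evidence that trades accuracy against complexity.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .variational_laplace import GaussianPrior, Posterior

__all__ = ["exclude_parameter", "set_tunable", "compare_free_energies"]


def exclude_parameter(prior: GaussianPrior, name: str) -> GaussianPrior:
    """Prior with ``name`` removed from the model (mean 0, variance 0).

    The parameter is fixed at 0 during inversion and contributes no KL
    term.  Idempotent.
    """
    out = prior.copy()
    i = out.index(name)
    out.mean[i] = 0.0
    out.cov[i, :] = 0.0
    out.cov[:, i] = 0.0
    return out


def set_tunable(prior: GaussianPrior, name: str, flag: bool) -> GaussianPrior:
    """Prior with the tunable flag of ``name`` set.

    ``flag=False`` freezes the parameter at its (possibly nonzero) prior
    mean without altering the mean; ``flag=True`` re-enables optimization.
    """
    out = prior.copy()
    out.tunable[out.index(name)] = bool(flag)
    return out


def compare_free_energies(
    results: Sequence[tuple[str, Posterior]],
    reference_label: str | None = None,
) -> pd.DataFrame:
    """Rank inversions of the same data by free energy.

    Returns a DataFrame (sorted by descending F) with columns ``label``,
    ``F``, ``relative_F`` (F - F_reference) and ``best``.  All posteriors
    must carry the same data hash; comparing fits of different data is an
    error.
    """
    if not results:
        raise ValueError("no inversion results to compare")
    labels = [label for label, _ in results]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate model labels in {labels}")
    hashes = {p.data_hash for _, p in results}
    if len(hashes) > 1:
        raise ValueError(
            "inversions were run on different data (mismatched data hashes); "
            "free energies are not comparable"
        )
    if reference_label is None:
        reference_label = labels[0]
    if reference_label not in labels:
        raise KeyError(f"reference label {reference_label!r} not among {labels}")
    F = {label: float(p.free_energy) for label, p in results}
    F_ref = F[reference_label]
    table = pd.DataFrame(
        {
            "label": labels,
            "F": [F[l] for l in labels],
            "relative_F": [F[l] - F_ref for l in labels],
        }
    ).sort_values("F", ascending=False, ignore_index=True)
    table["best"] = table["F"] == table["F"].max()
    return table
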