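"""File I/O: delimited time series, CSD/posterior JSON, model configuration.

Time series travel as tab-separated text with a ``# TR=<seconds>`` metadata
line and a header of region labels; posteriors, scenarios and comparison
tables are JSON documents carrying a ``schema_version`` field.  A single
YAML or JSON configuration file can specify the model (regions,
connectivity priors, hemodynamic/BOLD defaults), the frequency grid and the
optimizer settings.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import hemodynamics as hemo
from . import neural_models as nm
from .spectral_forward import CrossSpectralDensity, FrequencyGrid
from .variational_laplace import GaussianPrior, Hyperparameters, Posterior, VLOptions

__all__ = [
    "load_timeseries",
    "save_timeseries",
    "save_csd",
    "load_csd",
    "save_posterior",
    "load_posterior",
    "load_config",
    "build_from_config",
]


class DataFormatError(ValueError):
    """Raised for malformed input files, with line/column context."""


def save_timeseries(path, Y, labels, tr: float) -> None:
    """Write a (n_time x n_regions) matrix as TSV with a TR metadata line."""
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2 or Y.shape[1] != len(labels):
        raise ValueError("data shape does not match the label count")
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# TR={tr:g}\n")
        fh.write("\t".join(labels) + "\n")
        for row in Y:
            fh.write("\t".join(f"{v:.10g}" for v in row) + "\n")


def load_timeseries(path, tr: float | None = None):
    """Read a region time-series table.

    Returns ``(matrix, labels, tr)`` with the matrix time-major.  TR is
    taken from a ``# TR=`` metadata line, or from the ``tr`` argument; it
    is an error if neither provides it.  Non-numeric cells are reported
    with their row and column.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    file_tr = None
    rows: list[list[str]] = []
    labels: list[str] | None = None
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.upper().startswith("TR="):
                    try:
                        file_tr = float(body[3:])
                    except ValueError:
                        raise DataFormatError(
                            f"{path}:{lineno}: malformed TR metadata {body!r}"
                        ) from None
                continue
            cells = line.split("\t") if "\t" in line else line.split(",")
            if labels is None:
                labels = [c.strip() for c in cells]
                continue
            rows.append(cells)
            if len(cells) != len(labels):
                raise DataFormatError(
                    f"{path}:{lineno}: expected {len(labels)} columns, got {len(cells)}"
                )
    if labels is None or not rows:
        raise DataFormatError(f"{path}: no header or data rows found")
    matrix = np.empty((len(rows), len(labels)))
    header_lines = 2 if file_tr is not None else 1
    for i, cells in enumerate(rows):
        for j, cell in enumerate(cells):
            try:
                matrix[i, j] = float(cell)
            except ValueError:
                raise DataFormatError(
                    f"{path}:{i + 1 + header_lines}: non-numeric value {cell!r} "
                    f"in column {labels[j]!r}"
                ) from None
    if not np.all(np.isfinite(matrix)):
        raise DataFormatError(f"{path}: non-finite values in the data")
    if matrix.shape[1] < 2:
        raise DataFormatError(
            f"{path}: cross-spectral analysis needs at least 2 channels"
        )
    out_tr = file_tr if file_tr is not None else tr
    if out_tr is None:
        raise DataFormatError(
            f"{path}: TR not found in the file and not supplied via config"
        )
    return matrix, labels, float(out_tr)


def save_csd(path, csd: CrossSpectralDensity) -> None:
    doc = {
        "schema_version": 1,
        "frequencies_hz": csd.grid.frequencies.tolist(),
        "labels": list(csd.labels),
        "real": csd.values.real.ravel().tolist(),
        "imag": csd.values.imag.ravel().tolist(),
    }
    Path(path).write_text(json.dumps(doc))


def load_csd(path) -> CrossSpectralDensity:
    doc = json.loads(Path(path).read_text())
    grid = FrequencyGrid(np.asarray(doc["frequencies_hz"], dtype=float))
    n_ch = len(doc["labels"])
    shape = (grid.n_freq, n_ch, n_ch)
    values = np.asarray(doc["real"], dtype=float).reshape(shape) + 1j * np.asarray(
        doc["imag"], dtype=float
    ).reshape(shape)
    return CrossSpectralDensity(values=values, grid=grid, labels=list(doc["labels"]))


def save_posterior(path, posterior: Posterior) -> None:
    Path(path).write_text(json.dumps(posterior.to_dict()))


def load_posterior(path) -> Posterior:
    return Posterior.from_dict(json.loads(Path(path).read_text()))


def load_config(path) -> dict:
    """Load a YAML or JSON configuration file into a dictionary."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def build_from_config(cfg: dict):
    """Build (model, prior, hyper, grid, opts) from a configuration mapping.

    Recognized sections (all optional except ``regions``):

    - ``regions``: list of labels;
    - ``connectivity``: ``prior_mean`` matrix and either ``free`` (list of
      names like ``a12``) or ``excluded`` (names removed from the model);
    - ``hemodynamics`` / ``bold``: keyword overrides of the defaults;
    - ``noise``: noise-spectrum defaults (``alpha_global`` etc.);
    - ``priors``: variances per group (connection, self, transit, noise);
    - ``grid``: ``f_min``, ``f_max``, ``n``;
    - ``optimizer``: any :class:`VLOptions` field.
    """
    from .synthetic_data import PRIOR_VARIANCES, scenario_prior

    labels = cfg.get("regions")
    if not labels:
        raise DataFormatError("configuration must list the model's regions")
    n = len(labels)
    conn_cfg = cfg.get("connectivity", {}) or {}
    A = np.asarray(conn_cfg.get("prior_mean", np.zeros((n, n))), dtype=float)
    hemo_cfg = cfg.get("hemodynamics", {}) or {}
    bold_cfg = dict(cfg.get("bold", {}) or {})
    field_strength = bold_cfg.pop("field_strength", None)
    if field_strength is not None:
        bold = hemo.bold_params_for_field(
            field_strength,
            TE=bold_cfg.get("TE", 0.04),
            V0=bold_cfg.get("V0", 0.04),
        )
    else:
        bold = hemo.BoldParams(**bold_cfg)
    model = nm.assemble_circuit(
        regions=labels,
        connectivity=A,
        hemodynamic_params=hemo.HemodynamicParams(**hemo_cfg),
        bold_params=bold,
        noise_defaults=cfg.get("noise", {}) or {},
    )
    excluded = tuple(conn_cfg.get("excluded", ()))
    prior = scenario_prior(model, excluded=excluded)
    for group, value in (cfg.get("priors", {}) or {}).items():
        if group not in PRIOR_VARIANCES:
            raise DataFormatError(f"unknown prior group {group!r}")
    # per-group variance overrides
    overrides = cfg.get("priors", {}) or {}
    if overrides:
        var = prior.variances
        for i, name in enumerate(prior.names):
            if var[i] == 0:
                continue
            if name.startswith("a") and not name.startswith("alpha"):
                group = "self" if name[1] == name[2] else "connection"
            elif name.startswith("transit"):
                group = "transit"
            else:
                group = "noise"
            if group in overrides:
                var[i] = float(overrides[group])
        prior = GaussianPrior.from_diagonal(
            prior.names, prior.mean, var, tunable=prior.tunable
        )
    grid_cfg = cfg.get("grid", {}) or {}
    grid = FrequencyGrid.default_fmri(
        f_min=grid_cfg.get("f_min", 1.0 / 128.0),
        f_max=grid_cfg.get("f_max", 0.25),
        n=grid_cfg.get("n", 32),
    )
    opts = VLOptions(**(cfg.get("optimizer", {}) or {}))
    # hyper=None selects the calibrated default error model at fit time
    return model, prior, None, grid, opts
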