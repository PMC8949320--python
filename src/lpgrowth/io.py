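"""File formats and validation.

Long score tables and item-response tables travel as UTF-8 CSV with '.'
decimal separator; model/sampler configuration as TOML; fit summaries and
diagnostics as JSON sidecars.  Validation is strict: duplicate
person x timepoint rows and non-0-based or gapped timepoint codings are
rejected rather than silently repaired.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .params import (
    GammaPrior,
    GrowthModelSpec,
    GrowthParams,
    HalfTPrior,
    PriorSet,
    SamplerConfig,
    StudentTPrior,
)

SCORE_COLUMNS = ["person_id", "timepoint", "y"]
ITEM_COLUMNS = ["person_id", "timepoint", "subscale", "item_id", "correct", "rt_ms"]


class FormatError(ValueError):
    """Raised when an input file violates the expected format."""


def validate_scores(table: pd.DataFrame) -> pd.DataFrame:
    """Check a long score table: required columns, unique person x timepoint,
    contiguous 0-based timepoints, finite scores."""
    missing = [c for c in SCORE_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"missing column(s): {missing}")
    dup = table.duplicated(subset=["person_id", "timepoint"])
    if dup.any():
        rows = (np.flatnonzero(dup) + 2).tolist()  # 1-based incl. header
        raise FormatError(f"duplicate person x timepoint rows at file line(s) {rows[:20]}")
    t = np.sort(table["timepoint"].unique())
    if t[0] != 0 or not np.array_equal(t, np.arange(len(t))):
        raise FormatError(
            f"timepoints must be coded 0..T-1 (intercept = initial level); got {t.tolist()}"
        )
    if not np.isfinite(table["y"].to_numpy(float)).all():
        raise FormatError("non-finite score values")
    return table


def read_scores(path: str | Path) -> pd.DataFrame:
    """Read and validate a long score CSV (person_id, timepoint, y)."""
    table = pd.read_csv(path, encoding="utf-8")
    return validate_scores(table)


def write_scores(table: pd.DataFrame, path: str | Path) -> None:
    """Validate and write a long score CSV."""
    validate_scores(table)
    table.to_csv(path, index=False, encoding="utf-8")


def read_item_responses(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in ITEM_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"missing column(s): {missing}")
    if not table["correct"].isin((0, 1)).all():
        raise FormatError("correct must be 0/1")
    if (table["rt_ms"] <= 0).any():
        raise FormatError("rt_ms must be positive")
    return table


def write_item_responses(table: pd.DataFrame, path: str | Path) -> None:
    table[ITEM_COLUMNS].to_csv(path, index=False, encoding="utf-8")


# ---------------------------------------------------------------------------
# configuration


def growth_params_from_dict(d: dict) -> GrowthParams:
    return GrowthParams(**d)


def spec_from_dict(d: dict) -> GrowthModelSpec:
    d = dict(d)
    priors = d.pop("priors", None)
    if priors is not None:
        kw = {}
        if "intercept_mean_prior" in priors:
            v = priors["intercept_mean_prior"]
            kw["intercept_mean_prior"] = None if v is None else StudentTPrior(**v)
        if "sd_prior" in priors:
            kw["sd_prior"] = HalfTPrior(**priors["sd_prior"])
        if "sigma_prior" in priors:
            kw["sigma_prior"] = HalfTPrior(**priors["sigma_prior"])
        if "lkj_shape" in priors:
            kw["lkj_shape"] = priors["lkj_shape"]
        if "nu_prior" in priors:
            kw["nu_prior"] = GammaPrior(**priors["nu_prior"])
        d["priors"] = PriorSet(**kw)
    return GrowthModelSpec(**d)


def sampler_config_from_dict(d: dict) -> SamplerConfig:
    return SamplerConfig(**d)


def read_config(path: str | Path) -> dict:
    """Read a TOML configuration file."""
    import tomllib

    with open(path, "rb") as fh:
        return tomllib.load(fh)


def config_hash(obj) -> str:
    """Stable short hash of a configuration object for artifact stamping."""

    def _default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)

    blob = json.dumps(obj, default=_default, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_fit(fit, prefix: str | Path) -> tuple[Path, Path]:
    """Serialize a fit: population draws to CSV, diagnostics to a JSON
    sidecar.  Returns (draws_path, sidecar_path)."""
    prefix = Path(prefix)
    draws_path = prefix.with_suffix(".draws.csv")
    side_path = prefix.with_suffix(".diag.json")
    cols = {}
    for name, arr in fit.draws.items():
        cols[name] = arr.reshape(-1)
    chains, kept = next(iter(fit.draws.values())).shape
    frame = pd.DataFrame(cols)
    frame.insert(0, "chain", np.repeat(np.arange(chains), kept))
    frame.insert(1, "iteration", np.tile(np.arange(kept), chains))
    frame.to_csv(draws_path, index=False, encoding="utf-8")
    sidecar = {
        "family": fit.family,
        "chains": chains,
        "kept_per_chain": kept,
        "diagnostics": fit.diagnostics,
        "accept_rates": fit.accept_rates,
        "config": dataclasses.asdict(fit.config),
        "converged": fit.converged(),
    }
    side_path.write_text(json.dumps(sidecar, indent=2, default=float), encoding="utf-8")
    return draws_path, side_path
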