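"""Quantification of radiotracer uptake-plate assays.

Cultures grown in multi-well plates are exposed to a tritiated transporter
substrate for a fixed time in the presence of a transport blocker or solvent;
the radioactivity retained per well (cpm) is the single endpoint.  The module
computes per-condition means with SEM, the percent of the applied
radioactivity that was incorporated, percent inhibition relative to the
solvent control, and the fraction of uptake attributable to neurons (from a
paired neuron-free culture).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "UptakePlate",
    "ConditionSummary",
    "condition_summary",
    "percent_inhibition",
    "neuronal_fraction",
    "plate_summary",
    "read_plate_csv",
    "write_plate_csv",
]


class UptakeError(ValueError):
    pass


@dataclass
class UptakePlate:
    """One uptake plate: wells with condition labels plus optional metadata.

    ``applied_cpm`` is the total radioactivity each well was exposed to; it is
    an input (the cpm scale embeds an unknown counting efficiency, so it is
    never derived from specific activity).
    """

    wells: pd.DataFrame  # columns: well_id, condition, cpm
    applied_cpm: float | None = None
    plate_id: str = ""
    solvent_condition: str = "solvent"

    def __post_init__(self) -> None:
        required = {"well_id", "condition", "cpm"}
        if not required <= set(self.wells.columns):
            raise UptakeError(f"wells table needs columns {sorted(required)}")
        cpm = self.wells["cpm"].to_numpy(dtype=float)
        if not np.all(np.isfinite(cpm)) or np.any(cpm < 0):
            raise UptakeError("well cpm must be finite and non-negative")

    def condition_values(self, condition: str) -> np.ndarray:
        vals = self.wells.loc[self.wells["condition"] == condition, "cpm"]
        return vals.to_numpy(dtype=float)


class ConditionSummary(NamedTuple):
    mean: float
    sem: float
    n: int
    percent_of_applied: float | None
    sem_defined: bool


def condition_summary(plate: UptakePlate, condition: str) -> ConditionSummary:
    """Mean, SEM (sd/sqrt(n)), n and percent-of-applied for one condition.

    For a single well the SEM is reported as 0 with ``sem_defined=False``.
    When ``applied_cpm`` is missing the percentage is ``None``, never 0.
    """
    vals = plate.condition_values(condition)
    n = vals.size
    if n == 0:
        raise UptakeError(f"condition {condition!r} has no wells on plate {plate.plate_id!r}")
    mean = float(np.mean(vals))
    sem = float(np.std(vals, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    pct = 100.0 * mean / plate.applied_cpm if plate.applied_cpm else None
    return ConditionSummary(mean, sem, n, pct, sem_defined=n > 1)


def percent_inhibition(treated_mean: float, control_mean: float) -> float:
    """100 * (1 - treated/control); negative values mean uptake enhancement."""
    if control_mean <= 0:
        raise UptakeError("control mean must be positive")
    return 100.0 * (1.0 - treated_mean / control_mean)


def neuronal_fraction(full_culture_mean: float, neuron_free_mean: float) -> float:
    """Percent of uptake attributable to neurons.

    100 * (1 - neuron_free/full).  A neuron-free mean exceeding the
    full-culture mean yields a negative value, reported as computed with a
    warning.
    """
    if full_culture_mean <= 0:
        raise UptakeError("full-culture mean must be positive")
    if neuron_free_mean < 0:
        raise UptakeError("neuron-free mean must be non-negative")
    if neuron_free_mean > full_culture_mean:
        warnings.warn(
            "neuron-free uptake exceeds full-culture uptake; "
            "neuronal fraction is negative",
            stacklevel=2,
        )
    return 100.0 * (1.0 - neuron_free_mean / full_culture_mean)


def plate_summary(plate: UptakePlate) -> pd.DataFrame:
    """Per-condition summary with inhibition vs the plate's own solvent wells."""
    ctl = condition_summary(plate, plate.solvent_condition)
    rows = []
    for condition in plate.wells["condition"].unique():
        s = condition_summary(plate, condition)
        rows.append(
            {
                "plate_id": plate.plate_id,
                "condition": condition,
                "n": s.n,
                "mean_cpm": s.mean,
                "sem_cpm": s.sem,
                "percent_of_applied": s.percent_of_applied,
                "percent_inhibition": percent_inhibition(s.mean, ctl.mean),
            }
        )
    return pd.DataFrame(rows)


def read_plate_csv(path: str | Path, meta_path: str | Path | None = None) -> UptakePlate:
    df = pd.read_csv(path)
    meta = {}
    if meta_path is not None:
        with open(meta_path) as fh:
            meta = yaml.safe_load(fh) or {}
    plate_id = str(df["plate_id"].iloc[0]) if "plate_id" in df.columns else ""
    return UptakePlate(
        wells=df[["well_id", "condition", "cpm"]].copy(),
        applied_cpm=meta.get("applied_cpm"),
        plate_id=meta.get("plate_id", plate_id),
        solvent_condition=meta.get("solvent_condition", "solvent"),
    )


def write_plate_csv(plate: UptakePlate, path: str | Path) -> None:
    df = plate.wells.copy()
    df.insert(0, "plate_id", plate.plate_id)
    df.to_csv(path, index=False)
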