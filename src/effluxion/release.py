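"""Quantification of superfusion release assays.

Cultures pre-loaded with a radiotracer (e.g. [3H]MPP+) are continuously
superfused and timed fractions of the outflow are collected, typically 4-min
fractions starting after a 60-min washout.  Two depolarizing stimuli (S1 and
S2, e.g. at minutes 76 and 96) evoke transmitter release on top of the slowly
decaying basal efflux; a drug entering the superfusion buffer between the two
stimuli changes S2 relative to S1.  At the end of the experiment the
radioactivity still contained in the culture (the *residual*) is extracted and
counted, which makes the total tracer content at the start of every fraction
computable by backward summation.

The statistics implemented here:

``fractional_outflow``
    f_i = R_i / C_i, the radioactivity collected in fraction *i* as a fraction
    of the culture content at the start of that fraction.
``evoked_overflow``
    S% — stimulation-associated outflow in excess of a linearly interpolated
    basal outflow, as a percentage of the content at stimulus onset.
``ratio_stats``
    S2/S1 and LL/L1, within-culture ratios that cancel the large
    culture-to-culture variability of absolute release.
``normalize_to_solvent``
    drug-group ratios divided by the solvent-group mean of the same batch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "FractionSeries",
    "StimulationProtocol",
    "ReleaseSummary",
    "content_series",
    "fractional_outflow",
    "evoked_overflow",
    "ratio_stats",
    "summarize",
    "summarize_batch",
    "normalize_to_solvent",
    "read_fractions_csv",
    "write_fractions_csv",
    "read_protocol_yaml",
]


class ReleaseError(ValueError):
    """Raised for invalid fraction series or analysis-window geometry."""


@dataclass
class FractionSeries:
    """Per-culture time series of collected radioactivity.

    Parameters
    ----------
    counts : array-like
        Radioactivity retrieved per collected fraction (cpm, >= 0).
    residual : float
        Radioactivity remaining in the culture after the last fraction (cpm).
    t_start : array-like
        Start minute of each fraction; a strictly increasing uniform grid.
    """

    counts: np.ndarray
    residual: float
    t_start: np.ndarray
    culture_id: str = ""
    condition: str = "solvent"
    batch_id: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.t_start = np.asarray(self.t_start, dtype=float)
        if self.counts.ndim != 1 or self.counts.size == 0:
            raise ReleaseError("counts must be a non-empty 1-D array")
        if self.counts.size != self.t_start.size:
            raise ReleaseError("counts and t_start must have equal length")
        if not np.all(np.isfinite(self.counts)) or not math.isfinite(self.residual):
            raise ReleaseError("counts and residual must be finite")
        if np.any(self.counts < 0) or self.residual < 0:
            raise ReleaseError("counts and residual must be non-negative")
        dt = np.diff(self.t_start)
        if self.t_start.size > 1:
            if np.any(dt <= 0):
                raise ReleaseError("t_start must be strictly increasing")
            if not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-9):
                raise ReleaseError("t_start must lie on a uniform grid")

    @classmethod
    def from_counts(
        cls,
        counts: Sequence[float],
        residual: float,
        start_min: float = 60.0,
        fraction_len_min: float = 4.0,
        **kwargs,
    ) -> "FractionSeries":
        counts = np.asarray(counts, dtype=float)
        t = start_min + fraction_len_min * np.arange(counts.size)
        return cls(counts=counts, residual=residual, t_start=t, **kwargs)

    @property
    def fraction_len_min(self) -> float:
        if self.t_start.size < 2:
            return 4.0
        return float(self.t_start[1] - self.t_start[0])

    def scaled(self, factor: float) -> "FractionSeries":
        """Return a copy with all radioactivity multiplied by ``factor``."""
        return replace(self, counts=self.counts * factor, residual=self.residual * factor)


@dataclass
class StimulationProtocol:
    """Stimulus timing and analysis-window geometry.

    ``window_len`` fractions starting at the fraction containing the stimulus
    onset are counted as "during and after stimulation"; ``baseline_flank``
    fractions on each side of that window estimate the basal outflow under a
    linear-time-course assumption.
    """

    stim_times: Sequence[float] = (76.0, 96.0)
    stim_kind: str = "electrical"  # or "high_k"
    window_len: int = 2
    baseline_flank: int = 1
    drug_onset_min: float = 84.0

    def __post_init__(self) -> None:
        if self.window_len < 1 or self.baseline_flank < 1:
            raise ReleaseError("window_len and baseline_flank must be >= 1")

    def stim_fraction_index(self, series: FractionSeries, stim_index: int) -> int:
        """Index of the fraction whose half-open interval contains the stimulus."""
        t = self.stim_times[stim_index]
        dt = series.fraction_len_min
        idx = int(np.floor((t - series.t_start[0]) / dt + 1e-9))
        if idx < 0 or idx >= series.counts.size:
            raise ReleaseError(
                f"stimulus at minute {t} falls outside the collected fractions"
            )
        return idx

    def window_indices(self, series: FractionSeries, stim_index: int) -> np.ndarray:
        start = self.stim_fraction_index(series, stim_index)
        return np.arange(start, start + self.window_len)

    def validate_windows(self, series: FractionSeries) -> None:
        prev_end = -1
        for k in range(len(self.stim_times)):
            w = self.window_indices(series, k)
            lo = w[0] - self.baseline_flank
            hi = w[-1] + self.baseline_flank
            if lo < 0 or hi >= series.counts.size:
                raise ReleaseError(
                    f"analysis window plus flanks for stimulus {k} "
                    f"(fractions {lo}..{hi}) exceed the collected range"
                )
            if w[0] <= prev_end:
                raise ReleaseError("analysis windows of distinct stimuli overlap")
            prev_end = w[-1]


@dataclass
class ReleaseSummary:
    """All per-culture release statistics."""

    culture_id: str
    condition: str
    batch_id: str
    fractional_outflow: np.ndarray
    content_at_start: np.ndarray
    s_values: np.ndarray  # S% per stimulus
    s2_over_s1: float
    ll_over_l1: float
    evaluable: bool


def content_series(series: FractionSeries) -> np.ndarray:
    """Tracer content at the start of each fraction.

    C_i = residual + sum of the counts of fraction i and all later fractions;
    integer-exact when counts are integers.
    """
    return series.residual + np.cumsum(series.counts[::-1])[::-1]


def fractional_outflow(series: FractionSeries) -> np.ndarray:
    """f_i = R_i / C_i; scale-invariant rate of spontaneous efflux."""
    content = content_series(series)
    zero = np.flatnonzero(content <= 0)
    if zero.size:
        raise ReleaseError(f"zero content at fraction {int(zero[0])}")
    return series.counts / content


def evoked_overflow(
    series: FractionSeries, protocol: StimulationProtocol, stim_index: int
) -> float:
    """Stimulation-evoked overflow S%.

    Basal outflow per window fraction is the arithmetic mean of the flank
    fractions (linear time-course assumption); the excess of the window sum
    over ``window_len`` times that basal level is expressed as a percentage of
    the content at stimulus onset.  May be negative; not clipped.
    """
    window = protocol.window_indices(series, stim_index)
    lo = window[0] - protocol.baseline_flank
    hi = window[-1] + protocol.baseline_flank
    if lo < 0 or hi >= series.counts.size:
        raise ReleaseError(
            f"window plus flanks for stimulus {stim_index} outside the series"
        )
    flanks = np.concatenate(
        [series.counts[lo : window[0]], series.counts[window[-1] + 1 : hi + 1]]
    )
    basal = float(np.mean(flanks))
    excess = float(np.sum(series.counts[window])) - protocol.window_len * basal
    c_onset = content_series(series)[window[0]]
    if c_onset <= 0:
        raise ReleaseError("zero content at stimulation onset")
    return 100.0 * excess / c_onset


def ratio_stats(
    series: FractionSeries,
    protocol: StimulationProtocol,
    ll_mode: str = "fractional",
) -> tuple[float, float]:
    """(S2/S1, LL/L1) for a two-stimulus protocol.

    LL/L1 compares the last collected fraction with the fraction immediately
    preceding the S1 analysis window; by default it is computed on fractional
    outflow (a rate), ``ll_mode='counts'`` uses raw counts.  A non-positive S1
    yields ``nan`` for S2/S1 (the culture is flagged non-evaluable by
    :func:`summarize`) rather than an unbounded ratio.
    """
    if len(protocol.stim_times) < 2:
        raise ReleaseError("ratio statistics require two stimuli")
    protocol.validate_windows(series)
    s1 = evoked_overflow(series, protocol, 0)
    s2 = evoked_overflow(series, protocol, 1)
    s2_over_s1 = s2 / s1 if s1 > 0 else float("nan")
    l1_idx = protocol.window_indices(series, 0)[0] - 1
    if ll_mode == "fractional":
        f = fractional_outflow(series)
        l1, ll = f[l1_idx], f[-1]
    elif ll_mode == "counts":
        l1, ll = series.counts[l1_idx], series.counts[-1]
    else:
        raise ReleaseError(f"unknown ll_mode {ll_mode!r}")
    if l1 <= 0:
        raise ReleaseError("non-positive outflow in the fraction preceding S1")
    return s2_over_s1, float(ll / l1)


def summarize(
    series: FractionSeries,
    protocol: StimulationProtocol,
    ll_mode: str = "fractional",
) -> ReleaseSummary:
    """Full per-culture summary (S%, ratios, evaluability)."""
    protocol.validate_windows(series)
    s_values = np.array(
        [evoked_overflow(series, protocol, k) for k in range(len(protocol.stim_times))]
    )
    s2_over_s1, ll_over_l1 = ratio_stats(series, protocol, ll_mode=ll_mode)
    return ReleaseSummary(
        culture_id=series.culture_id,
        condition=series.condition,
        batch_id=series.batch_id,
        fractional_outflow=fractional_outflow(series),
        content_at_start=content_series(series),
        s_values=s_values,
        s2_over_s1=s2_over_s1,
        ll_over_l1=ll_over_l1,
        evaluable=bool(s_values[0] > 0),
    )


def summarize_batch(
    series_list: Iterable[FractionSeries],
    protocol: StimulationProtocol,
    ll_mode: str = "fractional",
) -> pd.DataFrame:
    """Tidy summary table, one row per culture."""
    rows = []
    for s in series_list:
        summ = summarize(s, protocol, ll_mode=ll_mode)
        rows.append(
            {
                "culture_id": summ.culture_id,
                "condition": summ.condition,
                "batch_id": summ.batch_id,
                "s1_pct": summ.s_values[0],
                "s2_pct": summ.s_values[1],
                "s2_over_s1": summ.s2_over_s1,
                "ll_over_l1": summ.ll_over_l1,
                "evaluable": summ.evaluable,
            }
        )
    return pd.DataFrame(rows)


def normalize_to_solvent(
    treated: Sequence[float], solvent: Sequence[float]
) -> np.ndarray:
    """Divide treated values by the solvent-group mean of the same batch."""
    solvent = np.asarray(solvent, dtype=float)
    if solvent.size == 0:
        raise ReleaseError("solvent group is empty")
    mean = float(np.mean(solvent))
    if mean <= 0:
        raise ReleaseError("solvent group mean must be positive")
    return np.asarray(treated, dtype=float) / mean


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

FRACTION_COLUMNS = ["culture_id", "condition", "batch_id", "fraction_index", "t_start_min", "cpm"]


def read_fractions_csv(path: str | Path) -> list[FractionSeries]:
    """Read a fraction-series table (residual rows have fraction_index = -1)."""
    df = pd.read_csv(path)
    missing = set(FRACTION_COLUMNS) - set(df.columns)
    if missing:
        raise ReleaseError(f"fraction CSV missing columns: {sorted(missing)}")
    out = []
    for culture_id, grp in df.groupby("culture_id", sort=False):
        res_rows = grp[grp["fraction_index"] < 0]
        if len(res_rows) != 1:
            raise ReleaseError(f"culture {culture_id!r} needs exactly one residual row")
        frac = grp[grp["fraction_index"] >= 0].sort_values("fraction_index")
        out.append(
            FractionSeries(
                counts=frac["cpm"].to_numpy(),
                residual=float(res_rows["cpm"].iloc[0]),
                t_start=frac["t_start_min"].to_numpy(),
                culture_id=str(culture_id),
                condition=str(frac["condition"].iloc[0]),
                batch_id=str(frac["batch_id"].iloc[0]),
            )
        )
    return out


def write_fractions_csv(series_list: Iterable[FractionSeries], path: str | Path) -> None:
    rows = []
    for s in series_list:
        for i, (t, c) in enumerate(zip(s.t_start, s.counts)):
            rows.append((s.culture_id, s.condition, s.batch_id, i, t, c))
        rows.append((s.culture_id, s.condition, s.batch_id, -1, float("nan"), s.residual))
    pd.DataFrame(rows, columns=FRACTION_COLUMNS).to_csv(path, index=False)


def read_protocol_yaml(path: str | Path) -> StimulationProtocol:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return StimulationProtocol(**raw)
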