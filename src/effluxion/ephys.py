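"""Patch-clamp sweep metrics: action-potential counts and charge transfer.

Two recording modes are supported.  In current clamp (CC), excitability is
probed with a family of 2-s depolarizing current steps of increasing
amplitude (50-300 pA in 50 pA increments); the metric is the summed number of
action potentials over the six steps.  In voltage clamp (VC), calcium
currents are evoked by brief depolarizations (30 ms to +10 mV from -80 mV);
the metric is the charge transfer Q_Ca, the time integral of the
baseline-subtracted current over the step, normalized per cell to the
pre-drug control sweeps (% of control) because absolute current amplitudes
vary strongly between neurons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SweepSet",
    "APCountResult",
    "ChargeResult",
    "detect_aps",
    "ap_protocol_count",
    "charge_transfer",
    "percent_of_control",
    "charge_timecourse",
    "read_sweeps_csv",
    "write_sweeps_csv",
]

CC_STEP_AMPLITUDES_PA = (50.0, 100.0, 150.0, 200.0, 250.0, 300.0)


class EphysError(ValueError):
    pass


@dataclass
class SweepSet:
    """Equal-length sweeps sharing a time base and step protocol.

    ``step_window`` is the (start, end) of the command step in seconds from
    sweep start.  ``junction_corrected`` records whether the liquid junction
    potential was already corrected at acquisition; traces are assumed
    corrected and the flag only gates a warning downstream.
    ``ground_truth`` may carry simulator-side truth (event lists, analytic
    charges) for validation and is ignored by the metrics.
    """

    mode: str  # "cc" or "vc"
    dt: float  # sampling interval, s
    sweeps: np.ndarray  # (n_sweeps, n_samples); mV for cc, pA for vc
    step_window: tuple[float, float]
    step_amplitudes: Sequence[float] = ()  # injected pA (cc) / command mV (vc)
    cell_id: str = ""
    condition: str = "solvent"
    sweep_times: np.ndarray | None = None  # acquisition time of each sweep, s
    junction_corrected: bool = True
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sweeps = np.atleast_2d(np.asarray(self.sweeps, dtype=float))
        if self.dt <= 0:
            raise EphysError("dt must be positive")
        t0, t1 = self.step_window
        dur = self.sweeps.shape[1] * self.dt
        if not (0 <= t0 < t1 <= dur + 1e-12):
            raise EphysError("step window must lie inside the sweep duration")
        if self.sweep_times is not None:
            self.sweep_times = np.asarray(self.sweep_times, dtype=float)

    @property
    def n_sweeps(self) -> int:
        return self.sweeps.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.dt * np.arange(self.sweeps.shape[1])


@dataclass
class APCountResult:
    per_sweep_counts: np.ndarray
    total: int
    spike_times: list[np.ndarray]


@dataclass
class ChargeResult:
    q_ca: np.ndarray  # pC, signed (inward currents negative)
    percent_of_control: np.ndarray | None = None


def detect_aps(
    sweep: np.ndarray,
    dt: float,
    threshold_mv: float = 0.0,
    refractory_s: float = 0.002,
) -> np.ndarray:
    """Spike times from upward threshold crossings with a refractory period.

    A spike is an upward crossing of ``threshold_mv`` not preceded by another
    accepted crossing within ``refractory_s``.  Overshooting action potentials
    in sympathetic neurons cross 0 mV, hence the default threshold.
    """
    sweep = np.asarray(sweep, dtype=float)
    if not np.all(np.isfinite(sweep)):
        raise EphysError("sweep contains non-finite samples")
    above = sweep >= threshold_mv
    crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
    if crossings.size == 0:
        return np.empty(0)
    times = []
    last = -np.inf
    for idx in crossings:
        t = idx * dt
        if t - last >= refractory_s:
            times.append(t)
            last = t
    return np.asarray(times)


def ap_protocol_count(
    sweepset: SweepSet,
    threshold_mv: float = 0.0,
    refractory_s: float = 0.002,
    expected_sweeps: int = 6,
    allow_any_sweep_count: bool = False,
    include_post_step: bool = False,
) -> APCountResult:
    """Summed AP count over the step protocol.

    Counting is restricted to the step window by default (rebound spikes after
    the step are excluded).  The canonical protocol has 6 sweeps; other sweep
    counts require ``allow_any_sweep_count=True``.
    """
    if sweepset.mode != "cc":
        raise EphysError("AP counting requires current-clamp sweeps")
    if sweepset.n_sweeps != expected_sweeps and not allow_any_sweep_count:
        raise EphysError(
            f"expected {expected_sweeps} sweeps, got {sweepset.n_sweeps}; "
            "pass allow_any_sweep_count=True to override"
        )
    t0, t1 = sweepset.step_window
    spike_times, counts = [], []
    for sweep in sweepset.sweeps:
        times = detect_aps(sweep, sweepset.dt, threshold_mv, refractory_s)
        if not include_post_step:
            times = times[(times >= t0) & (times <= t1)]
        spike_times.append(times)
        counts.append(times.size)
    counts = np.asarray(counts)
    return APCountResult(counts, int(counts.sum()), spike_times)


def charge_transfer(
    sweep: np.ndarray,
    dt: float,
    window: tuple[float, float],
    baseline_policy: str | float = "pre",
    baseline_len_s: float = 0.005,
) -> float:
    """Charge moved during ``window`` in pC (trapezoidal integration).

    ``baseline_policy``: ``"pre"`` subtracts the mean of the ``baseline_len_s``
    segment immediately before the window; ``"none"`` subtracts nothing; a
    float subtracts that constant.  With current in pA and time in s the
    integral is directly in pC.  Inward currents give negative charge; report
    magnitudes with ``abs``.
    """
    sweep = np.asarray(sweep, dtype=float)
    t0, t1 = window
    i0, i1 = int(round(t0 / dt)), int(round(t1 / dt))
    if i0 < 0 or i1 >= sweep.size or i0 >= i1:
        raise EphysError("integration window exceeds the sweep")
    if baseline_policy == "pre":
        b0 = max(0, i0 - int(round(baseline_len_s / dt)))
        if b0 == i0:
            raise EphysError("no pre-window samples available for baseline")
        baseline = float(np.mean(sweep[b0:i0]))
    elif baseline_policy == "none":
        baseline = 0.0
    else:
        baseline = float(baseline_policy)
    return float(np.trapezoid(sweep[i0 : i1 + 1] - baseline, dx=dt))


def percent_of_control(
    q_ca: Sequence[float],
    sweep_times: Sequence[float],
    control_window: tuple[float, float],
) -> np.ndarray:
    """Each |q| as a percentage of the mean |q| of the control sweeps.

    Control sweeps are those whose acquisition time falls inside
    ``control_window`` (typically everything before drug onset); their
    percentages average to exactly 100.
    """
    q = np.abs(np.asarray(q_ca, dtype=float))
    t = np.asarray(sweep_times, dtype=float)
    if q.size != t.size:
        raise EphysError("q_ca and sweep_times must have equal length")
    mask = (t >= control_window[0]) & (t < control_window[1])
    if not mask.any():
        raise EphysError("no control sweeps inside the control window")
    ctl = float(np.mean(q[mask]))
    if ctl == 0:
        raise EphysError("zero mean control charge")
    return 100.0 * q / ctl


def charge_timecourse(
    sweepset: SweepSet,
    control_window: tuple[float, float] | None = None,
    window_offset_s: float = 0.0005,
    baseline_policy: str | float = "pre",
) -> ChargeResult:
    """Q_Ca per sweep and optional percent-of-control series.

    The integration window starts ``window_offset_s`` after the command step
    onset (excluding the capacitive settling transient) and ends at step end.
    """
    if sweepset.mode != "vc":
        raise EphysError("charge transfer requires voltage-clamp sweeps")
    t0, t1 = sweepset.step_window
    window = (t0 + window_offset_s, t1)
    q = np.array(
        [charge_transfer(s, sweepset.dt, window, baseline_policy) for s in sweepset.sweeps]
    )
    pct = None
    if control_window is not None:
        if sweepset.sweep_times is None:
            raise EphysError("percent-of-control needs sweep acquisition times")
        pct = percent_of_control(q, sweepset.sweep_times, control_window)
    return ChargeResult(q_ca=q, percent_of_control=pct)


# ---------------------------------------------------------------------------
# I/O — long-format sweep CSV with a YAML sidecar
# ---------------------------------------------------------------------------

def write_sweeps_csv(sweepset: SweepSet, path: str | Path, meta_path: str | Path) -> None:
    n_sweeps, n_samples = sweepset.sweeps.shape
    sweep_idx = np.repeat(np.arange(n_sweeps), n_samples)
    sample_idx = np.tile(np.arange(n_samples), n_sweeps)
    df = pd.DataFrame(
        {
            "cell_id": sweepset.cell_id,
            "sweep_index": sweep_idx,
            "sample_index": sample_idx,
            "t_s": sample_idx * sweepset.dt,
            "value": sweepset.sweeps.ravel(),
        }
    )
    df.to_csv(path, index=False)
    meta = {
        "mode": sweepset.mode,
        "dt": sweepset.dt,
        "units": "mV" if sweepset.mode == "cc" else "pA",
        "step_window": list(sweepset.step_window),
        "step_amplitudes": list(map(float, sweepset.step_amplitudes)),
        "condition": sweepset.condition,
        "junction_corrected": sweepset.junction_corrected,
        "sweep_times": None
        if sweepset.sweep_times is None
        else [float(x) for x in sweepset.sweep_times],
    }
    with open(meta_path, "w") as fh:
        yaml.safe_dump(meta, fh)


def read_sweeps_csv(path: str | Path, meta_path: str | Path) -> SweepSet:
    df = pd.read_csv(path)
    with open(meta_path) as fh:
        meta = yaml.safe_load(fh)
    sweeps = (
        df.sort_values(["sweep_index", "sample_index"])
        .groupby("sweep_index")["value"]
        .apply(np.asarray)
    )
    arr = np.vstack(sweeps.to_list())
    return SweepSet(
        mode=meta["mode"],
        dt=float(meta["dt"]),
        sweeps=arr,
        step_window=tuple(meta["step_window"]),
        step_amplitudes=meta.get("step_amplitudes", ()),
        cell_id=str(df["cell_id"].iloc[0]),
        condition=meta.get("condition", "solvent"),
        sweep_times=meta.get("sweep_times"),
        junction_corrected=meta.get("junction_corrected", True),
    )
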