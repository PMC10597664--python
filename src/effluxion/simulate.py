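"""Seeded simulators for every assay the pipeline consumes.

Three generators share one drug model (Hill inhibition of the evoked /
stimulus-driven signal):

* :func:`simulate_superfusion` — single-pool tracer depletion.  Per 4-min
  fraction the culture releases a basal portion ``Q * (1 - exp(-k_b g dt))``
  of its current content Q (g > 1 models the elevated spontaneous outflow
  under uptake blockade, active from drug onset); at each stimulus an extra
  ``e * (1 - Hill(c)) * Q`` is released and distributed 80/20 over the two
  analysis-window fractions (a 60-s stimulus early in a 4-min fraction with a
  washout tail).  Optional Poisson counting noise applies to the emitted
  counts only, so radioactivity is conserved exactly with noise off and in
  expectation with noise on.  The residual is the final pool content.

* :func:`simulate_uptake_plate` — per-condition well means scaled down by a
  configured inhibition fraction, with lognormal well-to-well variability.

* :func:`simulate_cc_sweeps` / :func:`simulate_vc_sweeps` — current-clamp
  step families with stereotyped spike waveforms (the generated event list is
  retained as detection ground truth) and voltage-clamp calcium-current
  transients ``-A (1-exp(-t/tau_act)) exp(-t/tau_dec)`` whose amplitude is
  scaled by ``1 - Hill(c)``; the closed-form window integral is retained as
  charge ground truth.

All randomness flows from one root seed through named
``numpy.random.SeedSequence`` substreams, so identical configs and seeds give
byte-identical outputs and adding one stream never perturbs another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np

from .dose_response import hill_inhibition
from .ephys import SweepSet, CC_STEP_AMPLITUDES_PA
from .release import FractionSeries, StimulationProtocol
from .uptake import UptakePlate

import pandas as pd

__all__ = [
    "DrugModel",
    "ReleaseSimConfig",
    "UptakeSimConfig",
    "CCSimConfig",
    "VCSimConfig",
    "SimConfig",
    "simulate_superfusion",
    "simulate_uptake_plate",
    "simulate_cc_sweeps",
    "simulate_vc_sweeps",
    "substream",
]


class SimConfigError(ValueError):
    pass


def substream(seed: int, *key: str) -> np.random.Generator:
    """Named child RNG stream of a root seed (stable across stage additions)."""
    import hashlib

    digest = [
        int.from_bytes(hashlib.sha256(str(k).encode()).digest()[:4], "big") % (2**31)
        for k in key
    ]
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=digest))


@dataclass
class DrugModel:
    """Hill inhibition of the stimulus-evoked signal, active from onset."""

    ic50_uM: float = 1.4
    nh: float = 1.95
    imax: float = 1.0
    # entering at minute 88 keeps the S1 post-flank (84-88) drug-free, so the
    # linear basal interpolation of the analysis stays unbiased
    onset_min: float = 88.0

    def inhibition(self, concentration_uM: float) -> float:
        if concentration_uM <= 0:
            return 0.0
        return float(hill_inhibition(concentration_uM, self.ic50_uM, self.nh, self.imax))


@dataclass
class ReleaseSimConfig:
    """Superfusion experiment: fractions of 4 min from minute 60, stimuli at
    76 (S1) and 96 (S2), drug entering between them."""

    initial_content_cpm: float = 1.0e6
    basal_rate_per_min: float = 0.002
    spontaneous_drug_gain: float = 1.5
    evoked_fraction: float = 0.02
    n_fractions: int = 13
    fraction_len_min: float = 4.0
    start_min: float = 60.0
    stim_times: tuple[float, ...] = (76.0, 96.0)
    window_split: tuple[float, ...] = (0.8, 0.2)
    poisson_noise: bool = True
    drug: DrugModel = field(default_factory=DrugModel)

    def protocol(self) -> StimulationProtocol:
        return StimulationProtocol(
            stim_times=self.stim_times,
            window_len=len(self.window_split),
            drug_onset_min=self.drug.onset_min,
        )


@dataclass
class UptakeSimConfig:
    """Endpoint uptake plate; means from the control mean and per-condition
    inhibition fractions, lognormal well-to-well scatter."""

    applied_cpm: float = 287.3e3  # derived: control cpm / fraction-of-applied
    control_mean_fraction: float = 0.0409
    condition_effects: Mapping[str, float] = field(
        default_factory=lambda: {"solvent": 0.0}
    )
    cv: float = 0.12
    n_wells: int = 6

    @property
    def control_mean_cpm(self) -> float:
        return self.applied_cpm * self.control_mean_fraction


@dataclass
class CCSimConfig:
    """Six 2-s current steps (50-300 pA); spike count per step shrinks with
    drug concentration via the Hill model."""

    base_counts: tuple[int, ...] = (2, 4, 6, 8, 10, 12)
    step_amplitudes_pA: tuple[float, ...] = CC_STEP_AMPLITUDES_PA
    dt_s: float = 2e-4  # 5 kHz is ample for the 0.5-ms spike waveforms
    pre_s: float = 0.25
    step_s: float = 2.0
    post_s: float = 0.25
    rest_mV: float = -65.0
    plateau_mV: float = -50.0
    spike_peak_mV: float = 25.0
    spike_sigma_s: float = 5e-4
    jitter: float = 0.2  # fraction of the inter-spike interval
    noise_sigma_mV: float = 1.0
    drug: DrugModel = field(default_factory=lambda: DrugModel(ic50_uM=1.1, nh=1.0))


@dataclass
class VCSimConfig:
    """30-ms depolarizations to +10 mV from -80 mV; inward Ca-current
    transient scaled by 1 - Hill(c)."""

    peak_pA: float = 2000.0
    tau_act_ms: float = 1.5
    tau_dec_ms: float = 50.0
    dt_s: float = 2e-5  # 50 kHz
    pre_s: float = 0.005
    step_s: float = 0.030
    post_s: float = 0.010
    noise_sigma_pA: float = 0.0
    n_sweeps: int = 1
    inter_sweep_s: float = 15.0
    drug: DrugModel = field(default_factory=lambda: DrugModel(ic50_uM=0.5, nh=1.0))


@dataclass
class SimConfig:
    """Root configuration: one seed, one block per experiment type."""

    seed: int = 0
    release: ReleaseSimConfig = field(default_factory=ReleaseSimConfig)
    uptake: UptakeSimConfig = field(default_factory=UptakeSimConfig)
    ephys_cc: CCSimConfig = field(default_factory=CCSimConfig)
    ephys_vc: VCSimConfig = field(default_factory=VCSimConfig)

    def as_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# superfusion
# ---------------------------------------------------------------------------

def simulate_superfusion(
    cfg: ReleaseSimConfig,
    condition: str = "solvent",
    concentration_uM: float = 0.0,
    rng: np.random.Generator | None = None,
    culture_id: str = "sim",
    batch_id: str = "batch0",
) -> FractionSeries:
    """One culture's fraction series under the single-pool depletion model.

    ``concentration_uM`` drives both the evoked-release suppression (from
    drug onset, via ``cfg.drug``) and the elevated spontaneous outflow
    (``spontaneous_drug_gain`` applies to fractions starting at or after
    onset whenever a drug is present).
    """
    if not (0 <= cfg.evoked_fraction < 1 and 0 < cfg.basal_rate_per_min):
        raise SimConfigError("rates and fractions out of range")
    rng = rng or np.random.default_rng(0)
    dtf = cfg.fraction_len_min
    t_starts = cfg.start_min + dtf * np.arange(cfg.n_fractions)
    drug_present = concentration_uM > 0
    suppression = cfg.drug.inhibition(concentration_uM)

    stim_fraction = {}
    for st in cfg.stim_times:
        idx = int(math.floor((st - cfg.start_min) / dtf + 1e-9))
        stim_fraction[idx] = st

    q = cfg.initial_content_cpm
    pending: dict[int, float] = {}  # fraction index -> evoked cpm due
    expected = np.empty(cfg.n_fractions)
    for i, t in enumerate(t_starts):
        gain = cfg.spontaneous_drug_gain if (drug_present and t >= cfg.drug.onset_min) else 1.0
        basal = q * (1.0 - math.exp(-cfg.basal_rate_per_min * gain * dtf))
        evoked_now = pending.pop(i, 0.0)
        if i in stim_fraction:
            st = stim_fraction[i]
            supp = suppression if (drug_present and st >= cfg.drug.onset_min) else 0.0
            total_evoked = cfg.evoked_fraction * (1.0 - supp) * q
            for k, w in enumerate(cfg.window_split):
                if k == 0:
                    evoked_now += w * total_evoked
                else:
                    pending[i + k] = pending.get(i + k, 0.0) + w * total_evoked
        release = basal + evoked_now
        if release > q:
            raise SimConfigError(
                "configured basal plus evoked release exceeds the remaining pool"
            )
        q -= release
        expected[i] = release
    if pending:
        raise SimConfigError("stimulation window extends past the collected fractions")

    counts = rng.poisson(expected).astype(float) if cfg.poisson_noise else expected
    return FractionSeries(
        counts=counts,
        residual=q,
        t_start=t_starts,
        culture_id=culture_id,
        condition=condition,
        batch_id=batch_id,
    )


# ---------------------------------------------------------------------------
# uptake plate
# ---------------------------------------------------------------------------

def simulate_uptake_plate(
    cfg: UptakeSimConfig,
    rng: np.random.Generator | None = None,
    plate_id: str = "plate0",
) -> UptakePlate:
    """Wells per condition with mean ``control * (1 - inhibition)`` and
    lognormal CV (exact means when cv = 0)."""
    rng = rng or np.random.default_rng(0)
    rows = []
    w = 0
    for condition, inhibition in cfg.condition_effects.items():
        if not 0.0 <= inhibition <= 1.0:
            raise SimConfigError(f"inhibition for {condition!r} outside [0, 1]")
        mean = cfg.control_mean_cpm * (1.0 - inhibition)
        if cfg.cv > 0 and mean > 0:
            sigma2 = math.log(1.0 + cfg.cv**2)
            mu = math.log(mean) - sigma2 / 2.0
            vals = rng.lognormal(mu, math.sqrt(sigma2), size=cfg.n_wells)
        else:
            vals = np.full(cfg.n_wells, mean)
        for v in vals:
            rows.append((f"W{w:03d}", condition, float(v)))
            w += 1
    wells = pd.DataFrame(rows, columns=["well_id", "condition", "cpm"])
    return UptakePlate(wells=wells, applied_cpm=cfg.applied_cpm, plate_id=plate_id)


# ---------------------------------------------------------------------------
# electrophysiology
# ---------------------------------------------------------------------------

def _spike_train_times(
    n: int, step_start: float, step_len: float, jitter: float, rng: np.random.Generator
) -> np.ndarray:
    """n jittered, regularly spaced event times within the step."""
    if n <= 0:
        return np.empty(0)
    interval = step_len / n
    base = step_start + (np.arange(n) + 0.5) * interval
    wobble = rng.uniform(-0.5, 0.5, size=n) * jitter * interval
    return np.sort(base + wobble)


def simulate_cc_sweeps(
    cfg: CCSimConfig,
    concentration_uM: float = 0.0,
    rng: np.random.Generator | None = None,
    cell_id: str = "cell0",
    condition: str = "solvent",
) -> SweepSet:
    """Six-step current-clamp family; per-step spike count is
    ``round(base_count * (1 - Hill(c)))``.  Ground-truth event times are kept
    in ``SweepSet.ground_truth['events']``."""
    rng = rng or np.random.default_rng(0)
    supp = cfg.drug.inhibition(concentration_uM)
    n_samples = int(round((cfg.pre_s + cfg.step_s + cfg.post_s) / cfg.dt_s))
    t = cfg.dt_s * np.arange(n_samples)
    in_step = (t >= cfg.pre_s) & (t < cfg.pre_s + cfg.step_s)
    sweeps, events = [], []
    for base in cfg.base_counts:
        count = int(round(base * (1.0 - supp)))
        v = np.full(n_samples, cfg.rest_mV)
        v[in_step] = cfg.plateau_mV
        times = _spike_train_times(count, cfg.pre_s, cfg.step_s, cfg.jitter, rng)
        amp = cfg.spike_peak_mV - cfg.plateau_mV
        for te in times:
            v += amp * np.exp(-0.5 * ((t - te) / cfg.spike_sigma_s) ** 2)
        if cfg.noise_sigma_mV > 0:
            v = v + rng.normal(0.0, cfg.noise_sigma_mV, size=n_samples)
        sweeps.append(v)
        events.append(times)
    return SweepSet(
        mode="cc",
        dt=cfg.dt_s,
        sweeps=np.vstack(sweeps),
        step_window=(cfg.pre_s, cfg.pre_s + cfg.step_s),
        step_amplitudes=cfg.step_amplitudes_pA,
        cell_id=cell_id,
        condition=condition,
        ground_truth={"events": events, "suppression": supp},
    )


def vc_analytic_charge(cfg: VCSimConfig, concentration_uM: float = 0.0) -> float:
    """Closed-form signed charge (pC) of the simulated Ca-current transient."""
    supp = cfg.drug.inhibition(concentration_uM)
    a = cfg.peak_pA * (1.0 - supp)
    ta, td = cfg.tau_act_ms / 1e3, cfg.tau_dec_ms / 1e3
    tc = 1.0 / (1.0 / ta + 1.0 / td)
    big_t = cfg.step_s
    return -a * (
        td * (1.0 - math.exp(-big_t / td)) - tc * (1.0 - math.exp(-big_t / tc))
    )


def simulate_vc_sweeps(
    cfg: VCSimConfig,
    concentration_uM: float = 0.0,
    rng: np.random.Generator | None = None,
    cell_id: str = "cell0",
    condition: str = "solvent",
) -> SweepSet:
    """Voltage-clamp sweeps with an inward double-exponential transient;
    analytic window charges are kept in ``ground_truth['q_pC']``."""
    rng = rng or np.random.default_rng(0)
    supp = cfg.drug.inhibition(concentration_uM)
    amp = cfg.peak_pA * (1.0 - supp)
    n_samples = int(round((cfg.pre_s + cfg.step_s + cfg.post_s) / cfg.dt_s))
    t = cfg.dt_s * np.arange(n_samples)
    ta, td = cfg.tau_act_ms / 1e3, cfg.tau_dec_ms / 1e3
    rel = t - cfg.pre_s
    in_step = (rel >= 0) & (rel < cfg.step_s)
    base_trace = np.zeros(n_samples)
    base_trace[in_step] = -amp * (1.0 - np.exp(-rel[in_step] / ta)) * np.exp(
        -rel[in_step] / td
    )
    tc = 1.0 / (1.0 / ta + 1.0 / td)
    big_t = cfg.step_s
    q_true = -amp * (
        td * (1.0 - math.exp(-big_t / td)) - tc * (1.0 - math.exp(-big_t / tc))
    )
    sweeps = []
    for _ in range(cfg.n_sweeps):
        tr = base_trace.copy()
        if cfg.noise_sigma_pA > 0:
            tr = tr + rng.normal(0.0, cfg.noise_sigma_pA, size=n_samples)
        sweeps.append(tr)
    return SweepSet(
        mode="vc",
        dt=cfg.dt_s,
        sweeps=np.vstack(sweeps),
        step_window=(cfg.pre_s, cfg.pre_s + cfg.step_s),
        step_amplitudes=[10.0],
        cell_id=cell_id,
        condition=condition,
        sweep_times=cfg.inter_sweep_s * np.arange(cfg.n_sweeps),
        ground_truth={"q_pC": np.full(cfg.n_sweeps, q_true), "suppression": supp},
    )
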