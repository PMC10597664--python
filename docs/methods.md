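# Methods

## Release quantification

The superfusion analysis assumes a well-mixed single tracer pool per culture.
Content bookkeeping is exact by construction: the content at the start of
fraction *i* is the residual extracted at the end of the experiment plus all
counts collected from fraction *i* onward, so C_i − C_{i+1} = R_i holds to
the integer when counts are integers, and every statistic built on it
(fractional outflow, S%, the ratios) is invariant under rescaling all
radioactivity by a positive constant — counting efficiency is an opaque
scale factor throughout.

Evoked overflow assumes basal efflux is *linear in time* across the analysis
window, estimated as the arithmetic mean of the flanking fractions.  Defaults
(configurable on `StimulationProtocol`):

| parameter        | default | rationale |
|------------------|---------|-----------|
| fraction length  | 4 min, grid from minute 60 | standard collection scheme after a 60-min washout |
| `stim_times`     | 76, 96 min | S1/S2 two-stimulus design |
| `window_len`     | 2 fractions | a 60-s stimulus early in a 4-min fraction releases a tail into the next fraction |
| `baseline_flank` | 1 fraction each side | smallest window over which linearity is credible |
| `drug_onset_min` | 84 (metadata) | enters between S1 and S2 |

Fractions are half-open intervals [t, t+4): a stimulus at minute 76 belongs
to the fraction starting at 76.  Negative S% values are retained (flooring
them would bias ratio statistics); a culture with S1 ≤ 0 is flagged
non-evaluable instead of emitting an unbounded S2/S1.  LL/L1 is computed on
fractional outflow by default (it is a *rate* comparison); a raw-counts mode
exists, and both are scale-invariant.  With true exponential depletion the
linear-basal assumption leaves a curvature error of order (k_b Δt)² —
about 10⁻⁴ in S% units at the default kinetics, which is why the "flat
series gives S% = 0" identity is tested at machine precision but simulator
round trips use 1% tolerances.

## Uptake quantification

Per-condition mean, SEM (sd/√n, flagged undefined at n = 1), percent of
applied radioactivity, percent inhibition 100·(1 − treated/control) against
the solvent wells of the *same plate* (controls travel with each plate; a
pooled mode exists), and the neuron-attributable share of uptake
100·(1 − neuron-free/full-culture).  The applied radioactivity per well is
an input, never derived from specific activity; the generator's default
(287.3 × 10³ cpm) is back-computed from a printed (mean cpm, percent) pair
and is flagged as derived.

## Electrophysiology metrics

Spike detection is a fixed-threshold upward crossing (default 0 mV — somatic
action potentials in sympathetic neurons overshoot 0 mV) with a 2-ms
refractory period; both are configurable.  The protocol count sums spikes
over the six 2-s current steps (50–300 pA), restricted to the step window —
rebound spikes after the step are excluded by default.

Charge transfer Q_Ca is the trapezoidal integral of the baseline-subtracted
current over the depolarization (pA × s = pC); the baseline is the mean of
the 5 ms before the window, and the window starts 0.5 ms after step onset to
exclude the capacitive settling transient (both configurable).  Inward
currents give negative charge; magnitudes are reported.  Because absolute
Ca-current amplitudes vary strongly between neurons, per-cell normalization
to the mean of the pre-drug control sweeps (% of control) is the primary
quantity.  Traces are assumed junction-potential corrected at acquisition; a
metadata flag records this.

## Hill fitting

`fit_hill` fits inhibition = I_max·cⁿᴴ/(cⁿᴴ + IC50ⁿᴴ) with IC50
parameterized as log IC50 (positivity by construction) on log₁₀
concentration.  Variants: 3-parameter default, fixed nH, fixed I_max —
different assays saturate differently (uptake plateaus near 80%, release/AP/
Ca currents near 100%), so the variant is per-assay configurable rather than
asserted globally.  Solvent (c = 0) points anchor the baseline in
`transform_response` and are excluded from the log-concentration regression.
Optimization uses trust-region least squares with tolerances at 10⁻¹⁵, which
recovers noise-free parameters to better than 10⁻⁶ relative; confidence
intervals are asymptotic t-based from the Jacobian at the optimum (the
standard nonlinear-regression report), with the IC50 interval formed on the
log scale and exponentiated.  R² = 1 − SS_res/SS_tot about the mean of the
transformed responses, unclipped.  Responses mapped outside [−0.05, 1.05]
are flagged but retained.

## Group comparisons

Mann-Whitney U uses the exact enumeration distribution when the combined
sample is ≤ 14 without ties and the tie-corrected normal approximation with
continuity correction otherwise (both forceable).  Kruskal-Wallis is
tie-corrected with a chi-squared reference; two-group input redirects to
Mann-Whitney with a note.  Dunn's post hoc z statistics are computed from
pooled-rank means with the standard tie term; the default comparison family
is each group vs the control (k − 1 comparisons, matching
concentration-vs-solvent designs) with Bonferroni adjustment — Holm,
no-adjustment and all-pairs families are available, since the exact
convention behind published "Dunn's multiple comparison" reports varies by
software.

## Synthetic-data generator

The generator's job is to produce data with the statistical structure the
analysis assumes, with known ground truth.

**Superfusion** (`ReleaseSimConfig`): single-pool depletion.  Defaults:
initial content 10⁶ cpm (fraction counts of a few thousand cpm, a realistic
scintillation-counting scale), basal rate 0.002 min⁻¹ (≈0.8% of content per
fraction, the slow washout typical after loading), evoked fraction 0.02 (S%
≈ 2 — small compared with content, as in real evoked-overflow data),
spontaneous drug gain 1.5 (uptake blockade elevates basal efflux), drug
model IC50 1.4 µM with nH 1.95 acting on evoked release only.  The
spontaneous-gain and evoked-suppression effects are deliberately separable
so the analysis cannot conflate them.  Evoked release is split 80/20 over
the two window fractions.  The drug enters at minute 88: a step-change
entry at 84 would fall inside S1's post-flank fraction (84–88) and bias the
basal interpolation of the *analysis* — with entry at 88 the S1 window and
flanks are drug-free, matching the assay's design logic.  Poisson noise
applies to emitted counts only, with the pool depleted by the expected
release, so the counts-plus-residual total is exactly conserved with noise
off and conserved in expectation with noise on.

**Uptake plates**: lognormal wells with configured mean inhibition per
condition and CV 0.12 (typical well-to-well scatter); CV 0 reproduces means
exactly.

**Current clamp**: baseline spike counts (2, 4, …, 12) across the six steps
(42 total), scaled by round(count·(1 − Hill(c))) with IC50 1.1 µM; spikes
are stereotyped Gaussian waveforms (peak +25 mV, σ 0.5 ms) at jittered
regular times within the step, on a −65/−50 mV rest/plateau, with Gaussian
noise (default σ 1 mV).  The generated event list is retained as detection
ground truth.  Sampling default 5 kHz — ample for 0.5-ms waveforms and an
order of magnitude lighter than acquisition-rate traces; configurable.

**Voltage clamp**: inward transient −A(1 − e^(−t/τ_act))e^(−t/τ_dec) with
A = 2000 pA, τ_act = 1.5 ms, τ_dec = 50 ms over the 30-ms step (sustained,
mildly decaying high-voltage-activated Ca current), A scaled by 1 − Hill(c)
with IC50 0.5 µM; the closed-form window integral is retained as ground
truth.  Sampling 50 kHz.

What the generator does **not** emulate: conductance-based spike dynamics,
vesicle-pool heterogeneity or facilitation/depression between S1 and S2,
chamber hydrodynamics and tubing dead volume, series-resistance and
filtering artifacts, or tritium decay.  Passing tests therefore demonstrate
that the analysis chain recovers known effects embedded in data satisfying
its own assumptions — not that those assumptions hold for any particular
recording rig.

## Pipeline and reproducibility

All randomness flows from one root seed through named `SeedSequence`
substreams (hash-derived spawn keys), so adding a stage never perturbs
another stage's draws and identical configs give byte-identical outputs.
Run manifests record a config hash and SHA-256 checksums of every output.

Problem sizes in the test suite are chosen to keep the full run at about ten
seconds while leaving the statistical checks meaningful: 500 replicates for
CI coverage, 2000 for the type-I-error band, 100 seeded virtual experiments
(6 conditions × 12 cultures) for end-to-end IC50 recovery, and a
120×60×40 grid-search oracle for the fit-optimality check.

## Known limitations

- The linear-basal S% estimator is slightly biased under strongly curved
  basal efflux or when a drug changes spontaneous outflow *within* a flank
  fraction; the generator avoids the latter by design (onset at a fraction
  boundary outside the S1 flanks), real data may not.
- Asymptotic CIs undercover mildly at small n or when I_max sits at its
  bound; coverage is verified at 90–99% under the tested conditions only.
- The exact Mann-Whitney path requires untied data; heavily tied small
  samples fall back to the tie-corrected approximation.
- `fit_hill` fits a single monotone site; biphasic relations are out of
  scope.
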