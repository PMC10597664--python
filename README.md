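# effluxion

Quantification pipeline for three workhorse assays of presynaptic
neuropharmacology, as used to characterize transport blockers (such as the
organic-cation-transporter inhibitor decynium-22) in primary sympathetic
neuron cultures:

1. **Superfusion release assays** — cultures pre-loaded with a tritiated
   transporter substrate (e.g. [³H]MPP⁺) are continuously washed; 4-min
   fractions of the outflow are collected and two depolarizing stimuli (S1,
   S2) are delivered, with a drug entering the buffer between them.
2. **Radiotracer uptake plates** — endpoint cpm per well after a 5-min
   exposure, with blockers or solvent.
3. **Perforated-patch recordings** — action-potential counts over a family of
   depolarizing current steps (current clamp), and charge transfer through
   voltage-activated Ca²⁺ channels during brief depolarizations (voltage
   clamp).

A seeded synthetic-data generator simulates all three experiment types, so
the entire pipeline runs and is testable without any external data.

## The statistics at the core

For a fraction series R₁…R_n with end-of-experiment residual, the content at
the start of fraction *i* is C_i = residual + Σ_{j≥i} R_j, the **fractional
outflow** is f_i = R_i/C_i, and the **evoked overflow** for a stimulation
window W with flanking baseline fractions B is

    S% = 100 · (Σ_{i∈W} R_i − |W| · mean_{i∈B} R_i) / C_onset ,

i.e. the outflow in excess of a linearly interpolated basal efflux, as a
percentage of content at stimulus onset.  Within-culture ratios **S2/S1**
(evoked) and **LL/L1** (spontaneous, last fraction vs the fraction before S1)
cancel the large culture-to-culture variability; drug-group ratios are
normalized to the solvent group of the same experiment.

Concentration–response data from any of the assays are mapped to a common
fraction-inhibited scale and fit with the Hill inhibition model

    inhibition(c) = I_max · cⁿᴴ / (cⁿᴴ + IC50ⁿᴴ)

by least squares on log₁₀ c, reporting IC50, nH, I_max with asymptotic
t-based 95% confidence intervals and R².  Group comparisons use Mann-Whitney
U (exact for small untied samples), Kruskal-Wallis, and Dunn's post hoc tests.

## Worked example

A complete seeded virtual experiment — solvent plus four drug concentrations,
six cultures each, Poisson counting noise — from one config file:

```yaml
# exp.yaml
seed: 42
release:
  n_cultures: 6
  concentrations_uM: [0.0, 0.3, 1.0, 3.0, 10.0]
  noise: true
```

```sh
effluxion run --config exp.yaml --out demo_run
```

This simulates the superfusion series (`fractions.csv`), quantifies each
culture (`summary.csv`), normalizes S2/S1 to solvent, fits the Hill model
(`fit.yaml`) and writes group tables with Kruskal-Wallis/Dunn statistics
(`group_tables.csv`), plus a checksum manifest.  The fitted parameters land
on the generator's truth (IC50 1.4 µM, nH 1.95):

```
ic50_uM: 1.4133027724564284
ci95_ic50_uM: [1.3608958283723775, 1.4677278635073299]
nH: 1.9426684851625045
imax: 1.0030826209578976
r_squared: 0.9983379199864225
```

and the group table shows the concentration-dependent suppression of evoked
release (mean normalized S2/S1 per condition, n = 6, Dunn-adjusted p vs
solvent):

```
condition    mean    sem     p_vs_solvent
solvent      1.000   0.006   —
drug_0.3uM   0.952   0.008   0.95
drug_1uM     0.661   0.007   0.073
drug_3uM     0.185   0.008   0.0016
drug_10uM    0.019   0.005   9.3e-06
```

The same building blocks are exposed per assay (`effluxion release`,
`effluxion uptake`, `effluxion ephys`, `effluxion fit`, `effluxion stats`,
`effluxion simulate`) and as a plain Python API (`effluxion.summarize`,
`effluxion.fit_hill`, …).

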