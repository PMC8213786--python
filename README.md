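# circanuc

Tools for studying the nuclear dynamics of the circadian clock proteins
PER2 and CRY1 in single human cells — the computational counterpart of
live-cell imaging experiments with endogenous fluorescent knock-in
reporters.

In such experiments, nuclear CRY1 turns out to be several-fold more
abundant than nuclear PER2, to oscillate with a smaller relative amplitude,
and to peak ~5 h later — observations at odds with the naive picture of a
stoichiometric PER2:CRY1 complex entering the nucleus as one unit.
`circanuc` bundles everything needed to model, emulate and analyze this
system:

- **`circanuc.model`** — an 8-variable ODE model of the PER2:CRY1
  negative-feedback loop (Hill-type repression by the nuclear complex only,
  association/dissociation in both compartments, complex-only nuclear
  import/export, monomer-only degradation), with limit-cycle
  characterization (period, peak/trough levels, relative amplitudes, phase
  delay).
- **`circanuc.ensemble`** — "artificial cell" ensembles by ±10% parameter
  randomization and the amplitude–period ("twist") correlation.
- **`circanuc.synth`** — a generator of synthetic single-cell fluorescence
  cohorts with realistic noise structure and known ground truth.
- **`circanuc.preprocess` / `circanuc.rhythm`** — the single-cell analysis
  pipeline: background subtraction, shared-trend removal, division-outlier
  imputation, rhythmicity testing in the 20–28 h band (Lomb–Scargle,
  JTK-style Kendall template test, harmonic regression; Fisher integration;
  BH-FDR 0.05), cosine fitting, circadian phase normalization and signed
  per-cell phase differences.
- **`circanuc.quantify`** — the semi-quantitative CRY1:PER2 abundance
  calculus with mScarlet-I/mClover3 brightness calibration (factor 4.3) and
  the 34 a.u. PER2 detection-floor offset.
- **`circanuc.fcs`** — fluorescence correlation spectroscopy: 3D-diffusion
  autocorrelation fitting, Atto-488 focal-volume calibration, background
  and fluorescent-fraction corrections, cpm/detection-floor QC.

The model at the core: mRNA dynamics follow

    dM_X/dt = v_X / (1 + (PC_n/K_rep)^h) − d_MX · M_X,   X ∈ {P, C}

with monomer/complex kinetics per the loop scheme; the observables are the
total nuclear signals PER2_nuc = P_n + PC_n and CRY1_nuc = C_n + PC_n.
Because the nuclear complex dissociates quickly and only monomers are
degraded, a long-lived nuclear CRY1 monomer integrates the dissociation
flux: one mechanism that yields high CRY1 abundance, damped CRY1 amplitude
and a delayed CRY1 peak at once. See `docs/methods.md` for the full model
description, parameter calibration and all statistical procedures.

## Worked example

Simulate the calibrated loop and characterize its limit cycle:

```python
>>> from circanuc import DEFAULT_PARAMS, simulate_clock, limit_cycle_metrics
>>> traj = simulate_clock(DEFAULT_PARAMS, duration=960.0)   # 40 days, 0.1 h grid
>>> m = limit_cycle_metrics(traj, transient=240.0)
>>> print(f"period {m.period:.2f} h, CRY1:PER2 peak ratio {m.peak_ratio:.2f}, "
...       f"rAMP ratio {m.ramp_per2 / m.ramp_cry1:.2f}, delay {m.phase_delay:.2f} h")
period 24.86 h, CRY1:PER2 peak ratio 4.94, rAMP ratio 3.18, delay 4.21 h
```

The nuclear CRY1 signal peaks higher, oscillates relatively less, and lags
the PER2 peak by several hours — the three signatures seen in double
knock-in cells.

Generate a synthetic 50-cell double knock-in cohort and push it through the
full analysis pipeline:

```python
>>> from circanuc.synth import builtin_presets, generate_experiment
>>> from circanuc.rhythm import analyze_experiment
>>> frames = generate_experiment(builtin_presets()["DKI-default"], 50, seed=1)
>>> cohort, diffs = analyze_experiment(frames)   # preprocess, test, fit, phases
>>> print(f"{cohort.groupby('cell_id')['rhythmic'].all().mean():.0%} of cells "
...       f"rhythmic in both channels; mean period "
...       f"{cohort.loc[cohort.rhythmic, 'period_h'].mean():.1f} h; "
...       f"median CRY1-after-PER2 delay {diffs.phase_diff_h.median():.2f} h")
100% of cells rhythmic in both channels; mean period 24.0 h; median CRY1-after-PER2 delay 5.41 h
```

The recovered cohort statistics match the generator's construction (period
24.0 ± 2.3 h, delay 5.4 h), validating the estimator chain end to end.

The same stages are available from a shell:

```sh
circanuc generate --preset DKI-default --n 50 --seed 1 --out cohort/
circanuc analyze --traces cohort/traces.csv --out results/
circanuc quantify --traces cohort/traces.csv --out ratios/
```

Every subcommand writes delimited tables plus a JSON manifest (config,
seed, versions) so each artifact is reproducible from its manifest alone.

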