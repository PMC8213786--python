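# Methods

## The PER2:CRY1 loop model

`circanuc.model` implements a deterministic ODE model of the core mammalian
circadian negative-feedback loop, reduced to the species that matter for
nuclear reporter dynamics: *Per2*/*Cry1* mRNAs (`M_P`, `M_C`), cytoplasmic
monomers (`P_c`, `C_c`), the cytoplasmic and nuclear PER2:CRY1 complexes
(`PC_c`, `PC_n`) and the nuclear monomers (`P_n`, `C_n`).  Design choices:

- Transcription of both genes is repressed by the nuclear complex alone,
  via a Hill term `v_X / (1 + (PC_n / K_rep)^h_rep)`.  No PER2
  phosphorylation module is included.
- Monomers associate and dissociate in both compartments; only the complex
  is imported into (and optionally exported from) the nucleus; monomers do
  not shuttle.
- Degradation acts on mRNAs and monomers only — the complex must dissociate
  before either partner can be degraded.  This makes nuclear monomer
  lifetimes, not complex turnover, the lever that shapes the two nuclear
  observables `PER2_nuc = P_n + PC_n` and `CRY1_nuc = C_n + PC_n`.

With nuclear dissociation faster than nuclear association, `PC_n`
dissociation acts as a common source for both nuclear monomers.  A
short-lived `P_n` then tracks the complex almost instantaneously, whereas a
long-lived `C_n` integrates the influx: a first-order low-pass filter with
corner frequency `d_Cn`.  For `d_Cn` well below the circadian angular
frequency this one mechanism simultaneously produces (i) a large standing
pool of nuclear CRY1 (high peak ratio), (ii) a damped relative amplitude of
CRY1 (the filter attenuates by `d_Cn / sqrt(d_Cn^2 + omega^2)`), and
(iii) a multi-hour phase lag of the CRY1 peak — the three qualitative
signatures the model is asked to reproduce.

### Default parameters

The default set is produced by `circanuc.calibrate.fit_default_parameters`
(fixed seed 20220): a 4000-point Latin-hypercube screen in log-parameter
space over physiological bounds, Nelder–Mead refinement of the eight best
candidates, a hard filter on three regime constraints (cytoplasmic
association flux dominates dissociation; nuclear dissociation dominates
association; `d_Pn > d_Cn`), and a least-squares objective over four
limit-cycle targets: period 24.7 h, nuclear CRY1:PER2 peak ratio ≈ 5,
rAMP(PER2)/rAMP(CRY1) ≈ 3, and a ≈ 5 h CRY1-after-PER2 peak delay.
Because several local optima reproduce those targets about equally well,
the final tie-break prefers the candidate whose ±10% ensembles most
robustly exhibit the positive period–amplitude correlation (median Spearman
p over three fixed ensemble seeds) — itself one of the observed behaviors
the model exists to explain, not a free dial.  The winning set is frozen as
`DEFAULT_PARAMS`; rerunning the calibration is deterministic.

### Numerics

`solve_ivp` with the stiffness-switching LSODA method, `rtol 1e-8` /
`atol 1e-10`, dense output resampled to a uniform 0.1 h grid.  Limit-cycle
metrics discard a 240 h transient by default; peaks and troughs are refined
by a three-point parabola, the period is the mean successive PER2_nuc
peak-to-peak interval, and an orbit counts as sustained when the interval
coefficient of variation is below 1% (with at least three peaks).  A
relative peak-prominence floor of 1e-4 prevents integrator ripple on a
converged fixed point from being read as an oscillation.  States are
validated non-negative on input, and excursions below −1e-6 nM abort with
the last valid time; the nuclear observables clip sub-tolerance negatives
to zero.

## Ensembles and twist

Cell-to-cell variability: each rate in the transcription, translation,
degradation, import and export classes (the default; association/
dissociation classes are selectable) is drawn independently and uniformly
from base ± 10%.  Non-oscillating or failed members are flagged and
excluded from summaries, never aborting the ensemble.  Twist is quantified
as the Spearman rank correlation between period and PER2 relative
amplitude — rank-based because the relation is visibly nonlinear — plus an
equal-width binned profile (6 bins, half-open intervals, SEM per bin).

## The synthetic microscopy generator

`circanuc.synth` emulates the statistical structure of hourly live-cell
imaging over three days (72 samples starting 2 h after synchronization):

- per-cell period ~ N(mean, SD) truncated to [20, 28] h; per-cell reference
  phase ~ N(12 h, 1.5 h).  The reference-phase mean is arbitrary (no
  absolute peak phase is encoded in the preset statistics) and documented
  here; the phase SD reflects a well-synchronized cohort.
- per channel: a cosine with relative amplitude `ramp`, cohort-mean peak
  level (a.u.) with lognormal cell-to-cell scatter (CV 0.2), and a fixed
  delay against the reference channel.  A `skewness` parameter exists for
  asymmetric waveforms but defaults to 0, since the downstream estimators
  are cosine-based.
- additive Gaussian background (level 100 a.u., SD 2) with a matched
  measured background series per cell; additive measurement noise
  (SD 4 a.u.); a linear trend (0.3 a.u./h) shared by all cells of a frame;
  rare positive autofluorescence spikes (0.2/cell/day, exponential
  amplitude × 30 a.u.); single-frame ×2 division outliers (0.33/cell/day)
  with recorded indices; and a per-channel detection floor below which
  signal is not detected.

The built-in presets encode the observed cohort statistics per knock-in
line (period means/SDs of 24.7 ± 2.0, 25.6 ± 1.6, 25.9 ± 2.0, 25.3 ± 1.7
and 24.0 ± 2.3 h; the 5.4 h CRY1-after-PER2 delay; the 8.0-fold true
CRY1:PER2 peak-level molecule ratio; the 4.3 mScarlet-I:mClover3 brightness
factor; the 34 a.u. PER2 detection floor; a 2× dosage for the bi-allelic
CRY1-mClover3 line).  Absolute a.u. peak levels are *constructed*, not
measured: PER2-mScarlet peaks at 136 a.u. so that with rAMP 0.6 its trough
sits exactly at the 34 a.u. floor (troughs indistinguishable from
background), and CRY1-mClover3 peaks at 253 a.u. so that the brightness-
corrected molecule ratio is exactly 8.0.  CRY1 rAMP is 0.2, one third of
PER2's.

What the generator does **not** emulate: pixel-level images and
segmentation error, photobleaching beyond a linear trend, skewed or damped
waveforms, period drift within a cell, and correlated (colored) noise.
Passing recovery tests therefore demonstrates the correctness of the
estimators under the encoded statistical structure, not performance on raw
microscopy images.

## Preprocessing

Pipeline order: background subtraction (mean of the matched background
series by default) → removal of the one linear trend shared by a frame →
imputation of division outliers → floor-to-zero for channels flagged
`sub_background_troughs` (PER2 by default) → mean normalization.  The
shared trend is fitted to pooled per-trace mean-centered intensities
(centering removes level differences between cells), and `slope·(t − t̄)`
is subtracted so each trace's mean is preserved exactly.  Division
imputation averages the nearest non-division neighbors on each side;
boundary flags copy their single neighbor; runs of adjacent flags share
flanking neighbors.  Bioluminescence series are instead divided by a
centered 24 h running average whose window shrinks at the edges
(preserving series length on 3-day records).

## Rhythmicity testing

Three detectors per trace, restricted to periods 20–28 h:

- **LS** — floating-mean Lomb–Scargle, standard normalization; the p-value
  of the band maximum uses the analytic Baluev upper bound with the scan
  measure `W = (f_max − f_min)·sqrt(4π·var(t))` adapted to the restricted
  band.
- **JTK** — Kendall-tau concordance against cosine templates on a lattice
  of periods 20–28 h (step 1 h) and phases (step dt).  The lattice maximum
  is referred to its *exact* distribution-free null: the statistic depends
  only on the data ranks, so a cached Monte Carlo over rank permutations
  (50 000 draws, fixed internal seed) gives the reference distribution.  A
  Bonferroni correction over ~216 heavily correlated templates would be
  far conservative (empirical type-I error well below nominal); the
  permutation null keeps the test calibrated.
- **HR** — harmonic-regression R² maximized over a period grid (step
  0.25 h), referred to a cached Monte Carlo null for Gaussian noise; the
  statistic is location/scale invariant, so this null is parameter-free.
  An F-test at the best-fitting period alone would ignore the selection
  over periods.  HR is a documented stand-in for AR-spectral detection and
  can be deselected.

Monte Carlo nulls are cached per series shape with a fixed internal seed,
so p-values are deterministic; their granularity is 1/50 001.  Empirical
type-I error at α = 0.05 over 1000 white-noise series is 0.054–0.056 for
all three methods.  Method p-values are combined by Fisher's method (χ²
with 2k df) and cohorts are thresholded at Benjamini–Hochberg FDR ≤ 0.05.
Irregularly sampled series get the Lomb–Scargle p-value only.

## Cosine parameters and phase calculus

`fit_cosine` least-squares fits `m + A·cos(2π(t − φ)/τ)` by a period grid
search (0.05 h step, exact linear subproblem per candidate) plus bounded
local refinement; `A ≥ 0`, `φ ∈ [0, τ)`, boundary-period fits are flagged.
The fit requires at least two cycles at minper (40 h), which keeps the
skip-first-day reanalysis (data from 26 h onward of a 3-day recording)
admissible.  rAMP is defined as fitted amplitude / fitted mean.  Phases
are rescaled to circadian hours (`φ/τ × 24`, modulo 24; dual-channel cells
use the mean of their two periods), and the signed per-cell phase
difference takes whichever direction (delay `(φ_other − φ_ref) mod 24` or
advance `… − 24`) has magnitude below 8 circadian hours, falling back to
the candidate closer to the cohort mean; positive means the other channel
is delayed.  The difference is antisymmetric under swapping channels
whenever the magnitude is below 8 h.

## Abundance calculus

Peak values are extracted from background-subtracted (and, for PER2,
floored) series within a one-day window anchored at the recording start.
The brightness factor is `mean(scarlet peaks) / (mean(clover peaks) /
allele count)`, averaged over per-window estimates when day-1 and day-2
peaks are given separately.  The per-cell ratio is
`clover × factor / (scarlet + offset)` with defaults factor 4.3 and offset
34 a.u. — both configuration values, not constants baked into the formula.
On the synthetic double knock-in cohort the day-1 peak-ratio mean recovers
the constructed 8-fold ratio to within a few percent; the small negative
bias comes from the noise-driven minimum subtracted by the floor step.

## FCS

Single-component free 3D diffusion in a 3D-Gaussian volume,
`G(τ) = (1/N)(1 + τ/τ_D)^{-1}(1 + τ/(κ²τ_D))^{-1/2}`; no triplet term.
κ is fixed at the calibration value (default 5) rather than fitted — short
acquisitions constrain it poorly.  Fits minimize relative residuals
(weighting log-spaced decades evenly) via Levenberg–Marquardt.  The focal
volume is calibrated from a reference dye: `w0 = sqrt(4 D_ref τ_D,ref)`,
`V_eff = π^{3/2} w0³ κ` (this convention is stated explicitly because
definitions differ between instruments); concentration is
`N / (V_eff N_A)`, i.e. 1.661 nM per molecule per fL.  Background
correction multiplies by `(F_m − F_BG)²/F_m²` and the result is divided by
the fluorescent fraction (default 0.6).  The cpm filter removes valid fits
with counts-per-molecule below `mean(cpm) − 3·SD(cpm within the
interquartile range)` — one reading of an ambiguous rule, configurable —
while below-background or failed fits are assigned the detection floor
(0.11 nM, or the cohort's 10th percentile with `floor='auto'`) rather than
filtered.  Synthetic cohorts invert the analysis chain exactly: apparent N
is inflated by `(F_m/(F_m − F_BG))²` and reduced by the fluorescent
fraction, so the fit → correction → division chain recovers the preset
concentration; instrument count rates (cpm 3000 counts/s, background
1000 ± 100 counts/s) are constructed plausible values, documented as such.

## Problem sizes and determinism

Simulations use 40-day runs (960 h) for default-parameter
characterization, 480 h (240 h transient) for ensemble members, 50-cell
imaging cohorts, 1000-series null calibrations and 20-curve FCS cohorts;
these sizes make every result stable at the quoted tolerances while
keeping the full suite fast.  All stochastic components accept explicit
seeds; the acceptance script derives all sub-seeds from its single
`--seed` argument.

## Known limitations

- The ODE parameter set is calibrated to observable targets, not fitted to
  trajectories; parameters are not claimed to be individually identified.
- The twist magnitude at ±10% variation is moderate (ρ ≈ 0.2–0.5 at
  n = 100), so its p-value fluctuates across ensemble seeds even though
  the sign is stable.
- JTK/HR reference nulls assume uniform sampling and exchangeability; the
  HR null additionally assumes Gaussian noise.
- The generator's division outliers are single-frame events; real division
  artifacts can span frames and displace nuclei.
- FCS fitting assumes a single diffusing component; mixtures bias τ_D
  toward an intensity-weighted average.
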