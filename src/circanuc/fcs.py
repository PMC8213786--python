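"""Fluorescence correlation spectroscopy: model, fitting and corrections.

Single-component free 3D diffusion through a 3D-Gaussian focal volume:

    G(tau) = (1/N) (1 + tau/tau_D)^-1 (1 + tau/(kappa^2 tau_D))^-1/2

with N the mean number of molecules in the effective volume
``V_eff = pi^(3/2) w0^3 kappa`` (fL for w0 in um), kappa the axial/lateral
structure parameter (fixed from calibration, not fitted per curve), and
``D = w0^2 / (4 tau_D)``.  The lateral radius w0 is calibrated from a
reference dye of known diffusion coefficient (Atto-488, D = 400 um^2/s).

Concentrations are corrected for uncorrelated background counts
(``c_corrected = c_measured (F_m - F_BG)^2 / F_m^2``) and for the fraction
of fluorophores in a non-fluorescent state (division by 0.6).  Quality
control removes fits with implausibly low counts-per-molecule and assigns a
detection-floor concentration (default 0.11 nM, or the cohort's 10th
percentile) to measurements indistinguishable from background.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from lmfit import Parameters, minimize as lm_minimize

__all__ = [
    "AVOGADRO",
    "FCSCurve",
    "FCSFit",
    "FocalVolume",
    "FCSPreset",
    "FCS_PRESETS",
    "model_autocorrelation",
    "generate_fcs_curve",
    "fit_autocorrelation",
    "calibrate_focal_volume",
    "correct_concentration",
    "qc_and_floor",
    "generate_fcs_cohort",
    "cell_mean_concentrations",
]

AVOGADRO = 6.02214076e23
#: nM corresponding to one molecule per fL: 1e9 / (N_A * 1e-15)
_NM_PER_MOLECULE_FL = 1e9 / (AVOGADRO * 1e-15)


def model_autocorrelation(tau, N: float, tau_D: float, kappa: float):
    """Autocorrelation of single-component 3D diffusion; G(0+) = 1/N."""
    tau = np.asarray(tau, dtype=float)
    if np.any(tau <= 0):
        raise ValueError("lag times must be > 0")
    if N <= 0 or tau_D <= 0 or kappa <= 0:
        raise ValueError("N, tau_D and kappa must be > 0")
    x = tau / tau_D
    return (1.0 / N) / ((1.0 + x) * np.sqrt(1.0 + x / kappa**2))


@dataclass
class FCSCurve:
    """Measured (or synthetic) autocorrelation curve with count rates."""

    lags: np.ndarray          # s, strictly increasing, > 0
    G: np.ndarray             # dimensionless
    F_m: float                # mean count rate, counts/s
    F_BG: float = 0.0         # background count rate, counts/s
    duration: float = 10.0    # s

    def __post_init__(self):
        self.lags = np.asarray(self.lags, dtype=float)
        self.G = np.asarray(self.G, dtype=float)
        if self.lags.shape != self.G.shape:
            raise ValueError("lags and G must have equal length")
        if np.any(self.lags <= 0) or np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be strictly increasing and > 0")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")


@dataclass(frozen=True)
class FocalVolume:
    """Calibrated 3D-Gaussian detection volume."""

    w0: float                 # lateral 1/e^2 radius, um
    kappa: float = 5.0        # axial / lateral ratio

    def __post_init__(self):
        if self.w0 <= 0:
            raise ValueError("w0 must be > 0")
        if self.kappa < 1:
            raise ValueError("kappa must be >= 1")

    @property
    def v_eff(self) -> float:
        """Effective volume pi^(3/2) w0^3 kappa in fL (= um^3)."""
        return float(np.pi**1.5 * self.w0**3 * self.kappa)


@dataclass
class FCSFit:
    """Fit result for one curve; concentrations in nM."""

    N: float = np.nan
    tau_D: float = np.nan       # s
    D: float = np.nan           # um^2/s
    cpm: float = np.nan         # counts per molecule, counts/s
    c_measured: float = np.nan
    c_corrected: float = np.nan
    c_final: float = np.nan
    converged: bool = True
    below_background: bool = False
    cpm_filtered: bool = False
    floored: bool = False
    curve: FCSCurve | None = field(default=None, repr=False)

    def replace(self, **kw) -> "FCSFit":
        return dataclasses.replace(self, **kw)


def generate_fcs_curve(
    N: float,
    tau_D: float,
    kappa: float = 5.0,
    F_m: float = 1e4,
    F_BG: float = 0.0,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
    n_lags: int = 96,
    lag_range: tuple[float, float] = (1e-6, 10.0),
) -> FCSCurve:
    """Synthetic autocorrelation on log-spaced lags, optionally with
    multiplicative Gaussian noise of relative SD ``noise_sd``."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lags = np.geomspace(lag_range[0], lag_range[1], n_lags)
    G = model_autocorrelation(lags, N, tau_D, kappa)
    if noise_sd > 0:
        G = G * (1.0 + noise_sd * rng.standard_normal(n_lags))
    return FCSCurve(lags=lags, G=G, F_m=F_m, F_BG=F_BG)


def fit_autocorrelation(
    curve: FCSCurve,
    kappa: float = 5.0,
    volume: FocalVolume | None = None,
) -> FCSFit:
    """Weighted least-squares fit of (N, tau_D) with kappa fixed.

    If a calibrated ``volume`` is given, the diffusion coefficient
    ``D = w0^2 / (4 tau_D)``, the measured concentration
    ``N / (V_eff N_A)`` (in nM) and cpm ``F_m / N`` are filled in.
    Non-convergence yields a flagged fit without values.
    """
    if curve.lags.size < 10:
        raise ValueError("need at least 10 lag points")
    g0 = float(np.max(curve.G[:5]))
    if g0 <= 0:
        return FCSFit(converged=False, curve=curve)
    params = Parameters()
    params.add("N", value=max(1.0 / g0, 1e-3), min=1e-6)
    half = np.argmin(np.abs(curve.G - 0.5 * g0))
    params.add("tau_D", value=float(curve.lags[half]), min=curve.lags[0] * 1e-2,
               max=curve.lags[-1] * 1e2)

    def residual(p):
        model = model_autocorrelation(curve.lags, p["N"].value, p["tau_D"].value, kappa)
        # relative residuals: weights the decades of a log-spaced curve evenly
        return (curve.G - model) / np.maximum(np.abs(model), 1e-12)

    try:
        res = lm_minimize(residual, params, method="leastsq")
    except Exception:
        return FCSFit(converged=False, curve=curve)
    if not res.success:
        return FCSFit(converged=False, curve=curve)
    N = float(res.params["N"].value)
    tau_D = float(res.params["tau_D"].value)
    fit = FCSFit(N=N, tau_D=tau_D, cpm=curve.F_m / N, curve=curve,
                 below_background=curve.F_m <= curve.F_BG)
    if volume is not None:
        fit.D = volume.w0**2 / (4.0 * tau_D)
        fit.c_measured = N / volume.v_eff * _NM_PER_MOLECULE_FL
    return fit


def calibrate_focal_volume(
    reference: FCSCurve,
    D_ref: float = 400.0,
    kappa: float = 5.0,
) -> FocalVolume:
    """Calibrate w0 from a reference dye of known diffusion coefficient
    (default Atto-488, 400 um^2/s): ``w0 = sqrt(4 D_ref tau_D_ref)``."""
    fit = fit_autocorrelation(reference, kappa=kappa)
    if not fit.converged:
        raise RuntimeError("reference fit did not converge")
    w0 = float(np.sqrt(4.0 * D_ref * fit.tau_D))
    return FocalVolume(w0=w0, kappa=kappa)


def correct_concentration(
    c_measured: float,
    F_m: float,
    F_BG: float,
    fluorescent_fraction: float = 0.6,
) -> float:
    """Background- and maturation-corrected concentration:
    ``c (F_m - F_BG)^2 / F_m^2 / fluorescent_fraction``."""
    if not 0 < fluorescent_fraction <= 1:
        raise ValueError("fluorescent_fraction must be in (0, 1]")
    if F_BG < 0:
        raise ValueError("F_BG must be >= 0")
    if F_m <= F_BG:
        raise ValueError("below background: F_m must exceed F_BG")
    return float(c_measured * (F_m - F_BG) ** 2 / F_m**2 / fluorescent_fraction)


def qc_and_floor(
    fits: list[FCSFit],
    floor: float | str = 0.11,
    fluorescent_fraction: float = 0.6,
    cpm_sd_multiple: float = 3.0,
) -> list[FCSFit]:
    """Apply the background correction, the cpm filter and the detection floor.

    Fits that are below background or failed get the floor concentration
    (flagged ``floored``); fits whose cpm falls below
    ``mean(cpm) - k SD(cpm restricted to the interquartile range)`` are
    removed.  With ``floor='auto'`` the floor is the cohort's 10th percentile
    of corrected above-background concentrations.
    """
    if not fits:
        raise ValueError("empty fit list")
    corrected: list[FCSFit] = []
    for f in fits:
        f = f.replace()
        if f.converged and not f.below_background:
            f.c_corrected = correct_concentration(
                f.c_measured, f.curve.F_m, f.curve.F_BG, fluorescent_fraction)
            f.c_final = f.c_corrected
        corrected.append(f)

    # the cpm brightness filter judges valid fits only; below-background
    # measurements are floored below rather than filtered
    def _valid(f):
        return f.converged and not f.below_background and np.isfinite(f.cpm)

    cpms = np.array([f.cpm for f in corrected if _valid(f)])
    if cpms.size >= 4:
        q1, q3 = np.percentile(cpms, [25, 75])
        inner = cpms[(cpms >= q1) & (cpms <= q3)]
        sd = float(np.std(inner, ddof=1)) if inner.size > 1 else 0.0
        threshold = float(np.mean(cpms)) - cpm_sd_multiple * sd
    else:
        threshold = -np.inf

    kept: list[FCSFit] = []
    for f in corrected:
        if _valid(f) and f.cpm < threshold:
            f.cpm_filtered = True
            continue
        kept.append(f)
    if not kept:
        raise ValueError("all fits removed by the cpm filter")

    if floor == "auto":
        above = [f.c_final for f in kept
                 if f.converged and not f.below_background and np.isfinite(f.c_final)]
        floor_value = float(np.percentile(above, 10)) if above else 0.0
    else:
        floor_value = float(floor)
    for f in kept:
        if not f.converged or f.below_background:
            f.c_final = floor_value
            f.floored = True
    return kept


# --- synthetic cohorts -----------------------------------------------------

@dataclass(frozen=True)
class FCSPreset:
    """Forward-model settings for a synthetic FCS cohort of one channel.

    Count-rate and noise characteristics of the instrument are not printed
    quantities; the values here are constructed to be plausible for a
    confocal setup with SPAD detection and are documented as such.
    """

    name: str
    concentration: float          # true total concentration, nM
    D: float                      # um^2/s
    cpm: float = 3000.0           # counts/s per fluorescent molecule
    F_BG_mean: float = 1000.0     # counts/s
    F_BG_sd: float = 100.0
    fluorescent_fraction: float = 0.6
    noise_sd: float = 0.0


FCS_PRESETS: dict[str, FCSPreset] = {
    "CRY1-mClover3": FCSPreset("CRY1-mClover3", concentration=4.7, D=2.3),
    "PER2-mScarlet": FCSPreset("PER2-mScarlet", concentration=0.42, D=1.0),
    "Atto-488": FCSPreset("Atto-488", concentration=10.0, D=400.0, F_BG_mean=0.0, F_BG_sd=0.0,
                          fluorescent_fraction=1.0),
}


def generate_fcs_cohort(
    preset: FCSPreset,
    volume: FocalVolume,
    n: int = 20,
    seed: int = 0,
) -> list[FCSCurve]:
    """Generate curves whose fitted-and-corrected concentrations recover the
    preset's true value.

    The forward model inverts the analysis chain: only a fraction of
    molecules fluoresce, and uncorrelated background counts inflate the
    apparent molecule number by ``(F_m / (F_m - F_BG))^2`` while diluting
    the amplitude, exactly the distortion the background correction undoes.
    """
    rng = np.random.default_rng(seed)
    tau_D = volume.w0**2 / (4.0 * preset.D)
    curves = []
    for _ in range(n):
        c_fluor = preset.fluorescent_fraction * preset.concentration
        n_fluor = c_fluor * volume.v_eff / _NM_PER_MOLECULE_FL
        f_sig = preset.cpm * n_fluor
        f_bg = max(rng.normal(preset.F_BG_mean, preset.F_BG_sd), 0.0) if preset.F_BG_sd else preset.F_BG_mean
        f_m = f_sig + f_bg
        n_apparent = n_fluor * (f_m / (f_m - f_bg)) ** 2 if f_m > f_bg else n_fluor
        curves.append(generate_fcs_curve(
            N=n_apparent, tau_D=tau_D, kappa=volume.kappa,
            F_m=f_m, F_BG=f_bg, noise_sd=preset.noise_sd, seed=rng))
    return curves


def cell_mean_concentrations(fits: list[FCSFit], areas_per_cell: int = 5) -> np.ndarray:
    """Mean final concentration per cell, grouping consecutive measurement
    areas (up to ``areas_per_cell``) into one cell."""
    c = np.array([f.c_final for f in fits if np.isfinite(f.c_final)])
    n_cells = int(np.ceil(c.size / areas_per_cell))
    return np.array([float(np.mean(c[i * areas_per_cell:(i + 1) * areas_per_cell]))
                     for i in range(n_cells)])
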