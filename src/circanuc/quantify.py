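"""Semi-quantitative CRY1:PER2 abundance calculus.

Comparing two proteins tagged with different fluorophores requires a
brightness calibration: mScarlet-I yields 4.3x the signal of mClover3 for
the same number of molecules (estimated from CRY1 lines carrying either
tag).  Because PER2 troughs are indistinguishable from background, each PER2
series is re-anchored at zero and its peaks carry a detection-floor offset
(34 a.u., the average nuclear background) as a lower bound on the
undetectable part.  The per-cell ratio is then

    ratio[CRY1/PER2] = (CRY1-mClover3 peak - BG) x 4.3
                       / ((PER2-mScarlet-I peak - BG) + 34)

evaluated on peak values extracted from a one-day window.  Factor and offset
are configuration defaults, not constants of the formula.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from circanuc.preprocess import (
    impute_division_outliers,
    floor_min_to_zero,
    remove_shared_linear_trend,
    subtract_background,
)
from circanuc.synth import CellTrace, FrameSet

__all__ = [
    "BRIGHTNESS_FACTOR_DEFAULT",
    "DETECTION_OFFSET_DEFAULT",
    "peak_in_window",
    "estimate_brightness_factor",
    "cry1_per2_ratio",
    "cohort_peak_comparison",
    "dki_peak_ratios",
]

BRIGHTNESS_FACTOR_DEFAULT = 4.3   # mScarlet-I : mClover3 signal per molecule
DETECTION_OFFSET_DEFAULT = 34.0   # a.u., PER2 detection-floor offset


def peak_in_window(trace: CellTrace, window: int) -> float:
    """Maximum of the (background-subtracted) series within day ``window``
    (1-based) of the recording, i.e. hours [24 (d-1), 24 d) after the first
    sample."""
    if window < 1:
        raise ValueError("window is a 1-based day index")
    rel = trace.time - trace.time[0]
    mask = (rel >= 24.0 * (window - 1)) & (rel < 24.0 * window)
    if not mask.any() or rel[-1] < 24.0 * window - trace.dt - 1e-9:
        raise ValueError(f"day-{window} window not fully inside the recording")
    return float(np.max(trace.intensity[mask]))


def estimate_brightness_factor(clover_peaks, scarlet_peaks, clover_allele_count: int = 1) -> float:
    """Brightness of mScarlet-I relative to mClover3 from CRY1 peak cohorts.

    ``factor = mean(scarlet) / (mean(clover) / allele_count)``.  Pass
    per-window sequences (e.g. ``[day1_list, day2_list]``) to average the
    window-wise estimates, or flat lists for a single pooled estimate.
    """
    if clover_allele_count < 1:
        raise ValueError("allele count must be >= 1")

    def _windows(x):
        x = list(x)
        if not x:
            raise ValueError("empty peak list")
        if np.ndim(x[0]) > 0:
            return [np.asarray(w, dtype=float) for w in x]
        return [np.asarray(x, dtype=float)]

    cl, sc = _windows(clover_peaks), _windows(scarlet_peaks)
    if len(cl) != len(sc):
        raise ValueError("clover and scarlet peak lists must have matching windows")
    factors = []
    for c, s in zip(cl, sc):
        cm = float(np.mean(c)) / clover_allele_count
        if cm <= 0:
            raise ValueError("clover peak mean must be > 0")
        factors.append(float(np.mean(s)) / cm)
    return float(np.mean(factors))


def cry1_per2_ratio(
    clover_signal,
    scarlet_signal,
    factor: float = BRIGHTNESS_FACTOR_DEFAULT,
    offset: float = DETECTION_OFFSET_DEFAULT,
):
    """CRY1:PER2 abundance ratio from background-subtracted peak signals:
    ``clover x factor / (scarlet + offset)``."""
    clover = np.asarray(clover_signal, dtype=float)
    scarlet = np.asarray(scarlet_signal, dtype=float)
    denom = scarlet + offset
    if np.any(denom <= 0):
        raise ValueError("non-positive denominator: scarlet signal + offset must be > 0")
    out = clover * factor / denom
    return float(out) if out.ndim == 0 else out


def cohort_peak_comparison(cohorts: dict[str, list], reference: str) -> pd.DataFrame:
    """Normalize every cohort's peak values to the reference cohort's mean."""
    if reference not in cohorts:
        raise KeyError(f"reference cohort {reference!r} not among {sorted(cohorts)}")
    ref = np.asarray(cohorts[reference], dtype=float)
    if ref.size == 0 or np.mean(ref) == 0:
        raise ValueError("reference cohort must be non-empty with non-zero mean")
    ref_mean = float(np.mean(ref))
    rows = []
    for name, values in cohorts.items():
        v = np.asarray(values, dtype=float) / ref_mean
        rows.append({"cohort": name, "n": v.size,
                     "mean": float(np.mean(v)), "median": float(np.median(v))})
    return pd.DataFrame(rows)


def dki_peak_ratios(
    frames: list[FrameSet],
    window: int = 1,
    factor: float = BRIGHTNESS_FACTOR_DEFAULT,
    offset: float = DETECTION_OFFSET_DEFAULT,
    clover_channel: str = "CRY1",
    scarlet_channel: str = "PER2",
) -> pd.DataFrame:
    """Per-cell CRY1:PER2 peak ratios for a dual-channel cohort.

    Traces are background-subtracted, frame-detrended and division-imputed;
    the scarlet (PER2) channel is additionally re-anchored at zero, matching
    how its peaks lose the sub-background trough contribution that the
    ``offset`` then compensates.
    """
    rows = []
    for frame in frames:
        if not frame.traces:
            continue
        prepped = remove_shared_linear_trend(
            frame.replace_traces([subtract_background(tr) for tr in frame.traces]))
        by_cell: dict[str, dict[str, CellTrace]] = {}
        for tr in prepped.traces:
            tr = impute_division_outliers(tr)
            if tr.channel == scarlet_channel:
                tr = floor_min_to_zero(tr)
            by_cell.setdefault(tr.cell_id, {})[tr.channel] = tr
        for cell_id, chans in by_cell.items():
            if clover_channel not in chans or scarlet_channel not in chans:
                continue
            clover_peak = peak_in_window(chans[clover_channel], window)
            scarlet_peak = peak_in_window(chans[scarlet_channel], window)
            rows.append({
                "cell_id": cell_id, "window": window,
                "clover_peak": clover_peak, "scarlet_peak": scarlet_peak,
                "ratio": cry1_per2_ratio(clover_peak, scarlet_peak, factor, offset),
            })
    return pd.DataFrame(rows)
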