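"""Preprocessing of fluorescence and bioluminescence time series.

The default fluorescence pipeline is: background subtraction, removal of the
linear trend shared by all cells of an imaging frame, imputation of
cell-division outliers, re-anchoring the minimum at zero for channels whose
troughs fall below background, and mean normalization.  Bioluminescence
traces are instead detrended by dividing by the 24-h running average.  Every
step returns a new trace and leaves the time grid untouched.
"""

from __future__ import annotations

import numpy as np

from circanuc.synth import CellTrace, FrameSet

__all__ = [
    "subtract_background",
    "remove_shared_linear_trend",
    "impute_division_outliers",
    "floor_min_to_zero",
    "normalize_by_mean",
    "detrend_running_average",
    "run_pipeline",
    "DEFAULT_PIPELINE",
]


def subtract_background(trace: CellTrace, mode: str = "mean") -> CellTrace:
    """Subtract the matched background series (``per-timepoint``) or its
    time average (``mean``, the imaging default)."""
    if trace.background is None:
        raise ValueError("trace has no background series")
    if mode == "mean":
        corrected = trace.intensity - float(np.mean(trace.background))
    elif mode == "per-timepoint":
        corrected = trace.intensity - trace.background
    else:
        raise ValueError(f"unknown mode {mode!r}; use 'mean' or 'per-timepoint'")
    return trace.replace(intensity=corrected)


def remove_shared_linear_trend(frame: FrameSet) -> FrameSet:
    """Remove the one linear trend shared by all cells of an imaging frame.

    A single slope is fitted by least squares to the pooled, per-trace
    mean-centered intensities (centering removes level differences between
    cells before the fit); ``slope * (t - mean(t))`` is then subtracted from
    every trace, which preserves each trace's mean exactly.
    """
    if not frame.traces:
        raise ValueError("frame has no traces")
    t = frame.traces[0].time
    if t.size < 3:
        raise ValueError("need at least 3 timepoints to fit a trend")
    tc = t - np.mean(t)
    pooled = np.concatenate([tr.intensity - np.mean(tr.intensity) for tr in frame.traces])
    tiled = np.tile(tc, len(frame.traces))
    slope = float(np.dot(tiled, pooled) / np.dot(tiled, tiled))
    out = [tr.replace(intensity=tr.intensity - slope * tc) for tr in frame.traces]
    return frame.replace_traces(out)


def impute_division_outliers(trace: CellTrace) -> CellTrace:
    """Replace intensities at division frames by the mean of the nearest
    non-division neighbors; at a boundary the single neighbor is used.
    Runs of adjacent division frames share the same flanking neighbors."""
    idx = np.asarray(trace.division_indices, dtype=int)
    if idx.size == 0:
        return trace.replace(intensity=trace.intensity.copy())
    n = trace.intensity.size
    flagged = np.zeros(n, dtype=bool)
    flagged[idx] = True
    if flagged.all():
        raise ValueError("all timepoints flagged as divisions; nothing to impute from")
    y = trace.intensity.copy()
    clean = np.nonzero(~flagged)[0]
    for i in idx:
        left = clean[clean < i]
        right = clean[clean > i]
        if left.size and right.size:
            y[i] = 0.5 * (trace.intensity[left[-1]] + trace.intensity[right[0]])
        elif left.size:
            y[i] = trace.intensity[left[-1]]
        else:
            y[i] = trace.intensity[right[0]]
    return trace.replace(intensity=y)


def floor_min_to_zero(trace: CellTrace) -> CellTrace:
    """Shift the series so its minimum is exactly zero (applied to channels
    whose troughs are indistinguishable from background)."""
    if trace.intensity.size == 0:
        raise ValueError("empty trace")
    return trace.replace(intensity=trace.intensity - float(np.min(trace.intensity)))


def normalize_by_mean(trace: CellTrace) -> CellTrace:
    """Divide by the series mean; the output has mean 1."""
    m = float(np.mean(trace.intensity))
    if m <= 0:
        raise ValueError(f"series mean must be > 0 to normalize, got {m:.4g}")
    return trace.replace(intensity=trace.intensity / m)


def detrend_running_average(values: np.ndarray, dt: float, window: float = 24.0) -> np.ndarray:
    """Divide a uniformly sampled series by its centered running average.

    The averaging window (default 24 h) shrinks near the edges so the series
    keeps its length.  Values must be strictly positive.
    """
    y = np.asarray(values, dtype=float)
    if np.any(y <= 0):
        raise ValueError("running-average detrend requires strictly positive values")
    half = int(round(0.5 * window / dt))
    if y.size <= 2 * half:
        raise ValueError("series must be longer than the averaging window")
    csum = np.concatenate([[0.0], np.cumsum(y)])
    i = np.arange(y.size)
    lo = np.maximum(i - half, 0)
    hi = np.minimum(i + half, y.size - 1)
    avg = (csum[hi + 1] - csum[lo]) / (hi + 1 - lo)
    return y / avg


#: Default ordered step list of the fluorescence pipeline.
DEFAULT_PIPELINE: list[dict] = [
    {"step": "subtract_background", "mode": "mean"},
    {"step": "remove_shared_linear_trend"},
    {"step": "impute_division_outliers"},
    {"step": "floor_min_to_zero", "channels": "sub_background_troughs"},
    {"step": "normalize_by_mean"},
]


def run_pipeline(
    frames: list[FrameSet],
    steps: list[dict] | None = None,
    floor_channels: set[str] | None = None,
) -> list[FrameSet]:
    """Apply an ordered step list to every trace of every frame.

    ``floor_channels`` names the channels to which ``floor_min_to_zero``
    applies when a step specifies ``channels: sub_background_troughs``
    (default: the PER2 channel).
    """
    if steps is None:
        steps = DEFAULT_PIPELINE
    if floor_channels is None:
        floor_channels = {"PER2"}
    out: list[FrameSet] = []
    for frame in frames:
        if not frame.traces:   # cell-free background frames pass through
            out.append(frame)
            continue
        current = frame
        for spec in steps:
            step = spec["step"]
            if step == "subtract_background":
                current = current.replace_traces(
                    [subtract_background(tr, mode=spec.get("mode", "mean")) for tr in current.traces])
            elif step == "remove_shared_linear_trend":
                current = remove_shared_linear_trend(current)
            elif step == "impute_division_outliers":
                current = current.replace_traces(
                    [impute_division_outliers(tr) for tr in current.traces])
            elif step == "floor_min_to_zero":
                current = current.replace_traces(
                    [floor_min_to_zero(tr) if tr.channel in floor_channels else tr
                     for tr in current.traces])
            elif step == "normalize_by_mean":
                current = current.replace_traces(
                    [normalize_by_mean(tr) for tr in current.traces])
            else:
                raise ValueError(f"unknown pipeline step {step!r}")
        out.append(current)
    return out
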