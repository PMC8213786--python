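"""Synthetic single-cell fluorescence time series.

Generates hourly nuclear-intensity traces (default 72 points starting 2 h
after synchronization) whose statistical structure mirrors live-cell imaging
of clock-protein fusion reporters: per-cell period and phase dispersion,
channel-specific waveform (relative amplitude, peak level, delay), additive
background with its own matched measurement series, a linear trend shared by
all cells of an imaging frame, rare autofluorescence spikes, single-frame
cell-division outliers, a channel detection floor, and additive measurement
noise.  Every trace carries its ground truth so downstream estimators can be
scored against it.

Built-in presets encode the cohort statistics observed for the knock-in
reporter lines (single knock-in = SKI, double knock-in = DKI): cohort period
means/SDs per line, the 5.4 h CRY1-after-PER2 delay, the 8.0-fold true
CRY1:PER2 peak-level ratio, the 4.3 mScarlet-I:mClover3 brightness factor and
the 34 a.u. PER2 detection floor.  Absolute a.u. peak levels are constructed
(not measured quantities) such that those printed ratios hold exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ChannelSpec",
    "GeneratorPreset",
    "CellTrace",
    "FrameSet",
    "generate_trace",
    "generate_experiment",
    "builtin_presets",
    "frames_to_table",
    "truth_table",
]


@dataclass(frozen=True)
class ChannelSpec:
    """One fluorescence channel of a preset.

    ``brightness`` is the fluorophore's signal per molecule relative to
    mClover3 (= 1.0).  ``ramp`` is the relative amplitude (cosine amplitude /
    mean) of the true signal; ``peak_level`` the cohort-mean true peak in
    a.u. with lognormal-like cell-to-cell CV ``peak_cv``.  ``delay`` shifts
    this channel's peak after the cell's reference phase (h).  Signal below
    ``detection_floor`` a.u. is not detected; channels whose troughs sit at
    or below that floor are flagged ``sub_background_troughs`` so the
    pipeline knows to re-anchor their minimum at zero.
    """

    name: str
    fluorophore: str
    brightness: float
    ramp: float
    peak_level: float
    peak_cv: float = 0.2
    delay: float = 0.0
    detection_floor: float = 0.0
    sub_background_troughs: bool = False
    alleles: int = 1
    skewness: float = 0.0

    def __post_init__(self):
        if self.brightness <= 0:
            raise ValueError("brightness must be > 0")
        if self.ramp < 0 or self.peak_cv < 0:
            raise ValueError("ramp and peak_cv must be >= 0")

    @property
    def mean_level(self) -> float:
        """True mean (baseline) a.u. implied by peak level and rAMP."""
        return self.peak_level / (1.0 + self.ramp)

    @property
    def trough_level(self) -> float:
        return self.mean_level * (1.0 - self.ramp)


@dataclass(frozen=True)
class GeneratorPreset:
    """Study-condition bundle for one knock-in line."""

    name: str
    channels: tuple[ChannelSpec, ...]
    period_mean: float
    period_sd: float
    period_bounds: tuple[float, float] = (20.0, 28.0)
    phase_mean: float = 12.0            # h after synchronization, reference channel
    phase_sd: float = 1.5
    n_timepoints: int = 72
    interval: float = 1.0               # h
    t_start: float = 2.0                # h after synchronization
    background_level: float = 100.0     # a.u.
    background_sd: float = 2.0
    trend_slope: float = 0.3            # a.u./h, shared within a frame
    spike_rate: float = 0.2             # autofluorescence events / cell / day
    spike_amplitude: float = 30.0       # a.u.
    division_rate: float = 0.33         # events / cell / day
    division_factor: float = 2.0        # multiplicative single-frame outlier
    noise_sd: float = 4.0               # a.u.

    def __post_init__(self):
        if self.interval <= 0 or self.n_timepoints < 2:
            raise ValueError("need interval > 0 and at least 2 timepoints")
        if self.period_sd < 0 or self.phase_sd < 0 or self.background_sd < 0 or self.noise_sd < 0:
            raise ValueError("all SDs must be >= 0")
        if not self.channels:
            raise ValueError("preset needs at least one channel")

    @property
    def time(self) -> np.ndarray:
        return self.t_start + self.interval * np.arange(self.n_timepoints)

    def channel(self, name: str) -> ChannelSpec:
        for ch in self.channels:
            if ch.name == name:
                return ch
        raise KeyError(f"unknown channel {name!r}; have {[c.name for c in self.channels]}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["channels"] = [dataclasses.asdict(c) for c in self.channels]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorPreset":
        d = dict(d)
        d["channels"] = tuple(ChannelSpec(**c) for c in d["channels"])
        if "period_bounds" in d:
            d["period_bounds"] = tuple(d["period_bounds"])
        return cls(**d)


@dataclass
class CellTrace:
    """One cell's fluorescence time series in one channel."""

    cell_id: str
    frame_id: str
    channel: str
    time: np.ndarray
    intensity: np.ndarray
    background: np.ndarray | None = None
    division_indices: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    truth: dict | None = None

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.shape != self.time.shape:
            raise ValueError("intensity and time must have equal length")
        if self.background is not None:
            self.background = np.asarray(self.background, dtype=float)
            if self.background.shape != self.time.shape:
                raise ValueError("background and time must have equal length")
        self.division_indices = np.asarray(self.division_indices, dtype=int)
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensities must be finite")

    def replace(self, **kw) -> "CellTrace":
        return dataclasses.replace(self, **kw)

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])


@dataclass
class FrameSet:
    """All traces sharing one imaging frame, plus the frame background."""

    frame_id: str
    traces: list[CellTrace]
    background: np.ndarray | None = None
    time: np.ndarray | None = None

    def __post_init__(self):
        if self.traces:
            grid = self.traces[0].time
            for tr in self.traces[1:]:
                if not np.array_equal(tr.time, grid):
                    raise ValueError("all traces of a frame must share the time grid")
            self.time = grid

    def replace_traces(self, traces: list[CellTrace]) -> "FrameSet":
        return FrameSet(self.frame_id, traces, background=self.background, time=self.time)


def _cosine_signal(t, period, phase, mean, amplitude, skewness=0.0):
    theta = 2.0 * np.pi * (t - phase) / period
    if skewness:
        theta = theta - skewness * np.sin(theta)
    return mean + amplitude * np.cos(theta)


def generate_trace(
    preset: GeneratorPreset,
    channel: str,
    rng: np.random.Generator,
    cell_period: float | None = None,
    cell_phase: float | None = None,
    peak_scale: float | None = None,
    trend_slope: float | None = None,
    cell_id: str = "cell_000",
    frame_id: str = "frame_0",
) -> CellTrace:
    """Generate one channel trace; per-cell draws may be supplied externally
    so that the channels of one cell share period, phase and frame trend."""
    ch = preset.channel(channel)
    t = preset.time
    if cell_period is None:
        cell_period = _draw_period(preset, rng)
    if cell_phase is None:
        cell_phase = rng.normal(preset.phase_mean, preset.phase_sd)
    if peak_scale is None:
        peak_scale = _draw_peak_scale(ch, rng)
    slope = preset.trend_slope if trend_slope is None else trend_slope

    peak = ch.peak_level * peak_scale
    mean = peak / (1.0 + ch.ramp)
    amp = ch.ramp * mean
    phase = cell_phase + ch.delay
    signal = _cosine_signal(t, cell_period, phase, mean, amp, ch.skewness)
    detected = np.clip(signal - ch.detection_floor, 0.0, None)

    background = preset.background_level + rng.normal(0.0, preset.background_sd, t.size)
    noise = rng.normal(0.0, preset.noise_sd, t.size)

    n = t.size
    duration_days = (t[-1] - t[0]) / 24.0
    n_div = rng.poisson(preset.division_rate * duration_days)
    division_indices = np.unique(rng.integers(0, n, size=n_div)) if n_div else np.array([], dtype=int)

    # spikes come from a child stream so that changing the spike rate leaves
    # every other random draw of the trace untouched
    spike_rng = np.random.default_rng(int(rng.integers(0, 2**63)))
    n_spikes = spike_rng.poisson(preset.spike_rate * duration_days)
    spikes = np.zeros(n)
    if n_spikes:
        idx = spike_rng.integers(0, n, size=n_spikes)
        spikes[idx] += preset.spike_amplitude * spike_rng.exponential(1.0, size=n_spikes)

    intensity = detected + background + slope * (t - t[0]) + spikes + noise
    if division_indices.size:
        intensity[division_indices] *= preset.division_factor
    intensity = np.clip(intensity, 0.0, None)

    truth = {
        "period": float(cell_period),
        "phase": float(np.mod(phase, cell_period)),
        "delay": float(ch.delay),
        "peak_au": float(peak),
        "mean_au": float(mean),
        "amplitude_au": float(amp),
        "ramp": float(ch.ramp),
    }
    return CellTrace(cell_id, frame_id, channel, t, intensity, background, division_indices, truth)


def _draw_period(preset, rng):
    lo, hi = preset.period_bounds
    for _ in range(1000):
        tau = rng.normal(preset.period_mean, preset.period_sd)
        if lo <= tau <= hi:
            return tau
    raise RuntimeError("period distribution incompatible with bounds")


def _draw_peak_scale(ch, rng):
    # lognormal with unit mean keeps peak levels strictly positive
    if ch.peak_cv == 0:
        return 1.0
    sigma = np.sqrt(np.log(1.0 + ch.peak_cv**2))
    return rng.lognormal(-0.5 * sigma**2, sigma)


def generate_experiment(
    preset: GeneratorPreset,
    n_cells: int,
    n_frames: int = 1,
    seed: int = 0,
) -> list[FrameSet]:
    """Generate a cohort of cells distributed over imaging frames.

    Within one cell, all channels share the drawn period, reference phase and
    the frame's trend slope.  The returned list ends with a cell-free
    background frame, mirroring how background is measured in practice.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    frames: list[FrameSet] = []
    cell = 0
    per_frame = int(np.ceil(n_cells / n_frames))
    for f in range(n_frames):
        frame_id = f"frame_{f}"
        traces: list[CellTrace] = []
        slope = preset.trend_slope
        for _ in range(min(per_frame, n_cells - cell)):
            cell_id = f"cell_{cell:03d}"
            tau = _draw_period(preset, rng)
            phi = rng.normal(preset.phase_mean, preset.phase_sd)
            for ch in preset.channels:
                traces.append(generate_trace(
                    preset, ch.name, rng,
                    cell_period=tau, cell_phase=phi,
                    peak_scale=_draw_peak_scale(ch, rng),
                    trend_slope=slope, cell_id=cell_id, frame_id=frame_id,
                ))
            cell += 1
        frames.append(FrameSet(frame_id, traces))
    bg = preset.background_level + rng.normal(0.0, preset.background_sd, preset.n_timepoints)
    frames.append(FrameSet("background", [], background=bg, time=preset.time))
    return frames


# --- built-in presets ------------------------------------------------------

_BRIGHTNESS_SCARLET = 4.3       # mScarlet-I vs mClover3 signal per molecule
_PER2_FLOOR_SCARLET = 34.0      # a.u., PER2-mScarlet detection floor
_PER2_PEAK_SCARLET = 136.0      # a.u.; constructed so trough == floor at rAMP 0.6
_RATIO_TRUE = 8.0               # true CRY1:PER2 molecule peak ratio (DKI)
# CRY1-mClover3 peak such that clover_au * 4.3 / scarlet_au == 8.0
_CRY1_PEAK_CLOVER = _RATIO_TRUE * _PER2_PEAK_SCARLET / _BRIGHTNESS_SCARLET  # = 253.0 a.u.


def builtin_presets() -> dict[str, GeneratorPreset]:
    """Named presets encoding the observed cohort statistics per cell line.

    PER2 channels use rAMP 0.6 so that the waveform trough coincides with the
    detection floor (troughs indistinguishable from background); CRY1
    channels use rAMP 0.2, one third of PER2's.
    """
    per2_scarlet = ChannelSpec(
        "PER2", "mScarlet-I", brightness=_BRIGHTNESS_SCARLET, ramp=0.6,
        peak_level=_PER2_PEAK_SCARLET, detection_floor=_PER2_FLOOR_SCARLET,
        sub_background_troughs=True,
    )
    per2_clover = ChannelSpec(
        "PER2", "mClover3", brightness=1.0, ramp=0.6,
        peak_level=_PER2_PEAK_SCARLET / _BRIGHTNESS_SCARLET,
        detection_floor=_PER2_FLOOR_SCARLET / _BRIGHTNESS_SCARLET,
        sub_background_troughs=True,
    )
    cry1_clover = ChannelSpec(
        "CRY1", "mClover3", brightness=1.0, ramp=0.2,
        peak_level=_CRY1_PEAK_CLOVER, delay=5.4,
    )
    cry1_scarlet_ski = ChannelSpec(
        "CRY1", "mScarlet-I", brightness=_BRIGHTNESS_SCARLET, ramp=0.2,
        peak_level=_CRY1_PEAK_CLOVER * _BRIGHTNESS_SCARLET,
    )
    cry1_clover_ski = ChannelSpec(
        "CRY1", "mClover3", brightness=1.0, ramp=0.2,
        peak_level=2.0 * _CRY1_PEAK_CLOVER, alleles=2,
    )
    presets = [
        GeneratorPreset("DKI-default", (per2_scarlet, cry1_clover),
                        period_mean=24.0, period_sd=2.3),
        GeneratorPreset("SKI-CRY1-mScarlet", (cry1_scarlet_ski,),
                        period_mean=24.7, period_sd=2.0),
        GeneratorPreset("SKI-CRY1-mClover3", (cry1_clover_ski,),
                        period_mean=25.6, period_sd=1.6),
        GeneratorPreset("SKI-PER2-mScarlet", (per2_scarlet,),
                        period_mean=25.9, period_sd=2.0),
        GeneratorPreset("SKI-PER2-mClover3", (per2_clover,),
                        period_mean=25.3, period_sd=1.7),
    ]
    return {p.name: p for p in presets}


# --- tabular export --------------------------------------------------------

def frames_to_table(frames: list[FrameSet]) -> pd.DataFrame:
    """Long-format table: cell_id, frame_id, channel, time_h, intensity,
    background, is_division."""
    rows = []
    for fr in frames:
        for tr in fr.traces:
            div = np.zeros(tr.time.size, dtype=int)
            div[tr.division_indices] = 1
            rows.append(pd.DataFrame({
                "cell_id": tr.cell_id, "frame_id": tr.frame_id, "channel": tr.channel,
                "time_h": tr.time, "intensity": tr.intensity,
                "background": tr.background if tr.background is not None else np.nan,
                "is_division": div,
            }))
        if not fr.traces and fr.background is not None:
            rows.append(pd.DataFrame({
                "cell_id": "", "frame_id": fr.frame_id, "channel": "background",
                "time_h": fr.time, "intensity": fr.background,
                "background": fr.background, "is_division": 0,
            }))
    return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["cell_id", "frame_id", "channel", "time_h", "intensity", "background", "is_division"])


def truth_table(frames: list[FrameSet]) -> pd.DataFrame:
    """Sidecar table of per-trace ground truth."""
    rows = []
    for fr in frames:
        for tr in fr.traces:
            if tr.truth is not None:
                rows.append({"cell_id": tr.cell_id, "frame_id": tr.frame_id,
                             "channel": tr.channel, **tr.truth})
    return pd.DataFrame(rows)
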