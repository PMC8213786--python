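"""Delimited-table, config and curve-file I/O.

All artifacts are plain text: long-format CSV tables for traces and results,
flat ``key = value`` text for model parameter sets, YAML for generator
presets and pipeline configs, a small ``# key: value`` header block plus two
columns for FCS curves, and a JSON run manifest capturing config, seed and
versions so every artifact is reproducible from its manifest alone.
"""

from __future__ import annotations

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from circanuc.fcs import FCSCurve
from circanuc.model import ParameterSet
from circanuc.synth import CellTrace, FrameSet, GeneratorPreset

__all__ = [
    "read_table",
    "write_table",
    "read_params",
    "write_params",
    "read_preset",
    "write_preset",
    "read_fcs_curve",
    "write_fcs_curve",
    "frames_from_table",
    "write_manifest",
]

TRACE_SCHEMA = ["cell_id", "frame_id", "channel", "time_h", "intensity", "background", "is_division"]


def write_table(path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False, float_format="%.12g")


def read_table(path, schema: list[str] | None = None) -> pd.DataFrame:
    df = pd.read_csv(path)
    if schema is not None:
        missing = [c for c in schema if c not in df.columns]
        if missing:
            raise ValueError(f"table {path} is missing column(s): {missing}")
    return df


def write_params(path, params: ParameterSet) -> None:
    """Flat ``name = value`` text config."""
    lines = [f"{k} = {v:.12g}" for k, v in params.to_dict().items()]
    Path(path).write_text("\n".join(lines) + "\n")


def read_params(path) -> ParameterSet:
    d = {}
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"malformed parameter line: {line!r}")
        k, v = (s.strip() for s in line.split("=", 1))
        d[k] = float(v)
    return ParameterSet.from_dict(d)


def write_preset(path, preset: GeneratorPreset) -> None:
    Path(path).write_text(yaml.safe_dump(preset.to_dict(), sort_keys=False))


def read_preset(path) -> GeneratorPreset:
    return GeneratorPreset.from_dict(yaml.safe_load(Path(path).read_text()))


def read_pipeline_config(path) -> list[dict]:
    """Ordered preprocessing step list from a YAML file: a sequence of
    ``{step: name, ...options}`` mappings (bare strings allowed)."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, list):
        raise ValueError("pipeline config must be a YAML list of steps")
    steps = []
    for entry in raw:
        if isinstance(entry, str):
            steps.append({"step": entry})
        elif isinstance(entry, dict) and "step" in entry:
            steps.append(entry)
        else:
            raise ValueError(f"malformed pipeline step: {entry!r}")
    return steps


def write_fcs_curve(path, curve: FCSCurve) -> None:
    header = (f"# F_m: {curve.F_m:.12g}\n# F_BG: {curve.F_BG:.12g}\n"
              f"# duration: {curve.duration:.12g}\n")
    body = "\n".join(f"{lag:.12g},{g:.12g}" for lag, g in zip(curve.lags, curve.G))
    Path(path).write_text(header + "lag_s,G\n" + body + "\n")


def read_fcs_curve(path) -> FCSCurve:
    meta = {}
    rows = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#"):
            k, v = line[1:].split(":", 1)
            meta[k.strip()] = float(v)
        elif line and not line.startswith("lag_s"):
            lag, g = line.split(",")
            rows.append((float(lag), float(g)))
    lags, G = np.array(rows).T
    return FCSCurve(lags=lags, G=G, F_m=meta.get("F_m", 0.0),
                    F_BG=meta.get("F_BG", 0.0), duration=meta.get("duration", 10.0))


def frames_from_table(df: pd.DataFrame) -> list[FrameSet]:
    """Rebuild FrameSets from a long-format trace table."""
    missing = [c for c in TRACE_SCHEMA if c not in df.columns]
    if missing:
        raise ValueError(f"trace table is missing column(s): {missing}")
    frames = []
    for frame_id, fgrp in df.groupby("frame_id", sort=True):
        if (fgrp["channel"] == "background").all():
            sub = fgrp.sort_values("time_h")
            frames.append(FrameSet(str(frame_id), [],
                                   background=sub["intensity"].to_numpy(),
                                   time=sub["time_h"].to_numpy()))
            continue
        traces = []
        for (cell_id, channel), grp in fgrp.groupby(["cell_id", "channel"], sort=True):
            grp = grp.sort_values("time_h")
            bg = grp["background"].to_numpy()
            traces.append(CellTrace(
                cell_id=str(cell_id), frame_id=str(frame_id), channel=str(channel),
                time=grp["time_h"].to_numpy(),
                intensity=grp["intensity"].to_numpy(),
                background=None if np.all(np.isnan(bg)) else bg,
                division_indices=np.nonzero(grp["is_division"].to_numpy())[0],
            ))
        frames.append(FrameSet(str(frame_id), traces))
    return frames


def write_manifest(path, subcommand: str, config: dict, seed: int | None = None) -> None:
    import circanuc

    manifest = {
        "tool": "circanuc",
        "version": circanuc.__version__,
        "python": sys.version.split()[0],
        "subcommand": subcommand,
        "seed": seed,
        "config": {k: (str(v) if isinstance(v, Path) else v) for k, v in config.items()},
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
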