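"""Config and table I/O for the command-line workflow.

Geometry/kinematics configuration lives in YAML (or JSON — YAML is a
superset) with the same field names as the dataclasses; traces travel as
two-column CSV (``time_s, fluorescence_au``); treatment labels as CSV
(``trial_id, temperature``).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .geometry import EyeGeometry, StimulusKinematics
from .peaks import FluorescenceTrace
from .pipeline import AnalysisConfig

__all__ = [
    "load_config",
    "kinematics_from_config",
    "geometry_from_config",
    "analysis_from_config",
    "read_trace_csv",
    "write_trace_csv",
    "read_labels_csv",
]


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    return cfg


def kinematics_from_config(cfg: dict) -> StimulusKinematics:
    return StimulusKinematics(**cfg.get("kinematics", {}))


def geometry_from_config(cfg: dict) -> EyeGeometry:
    return EyeGeometry(**cfg.get("eye_geometry", {}))


def analysis_from_config(cfg: dict) -> AnalysisConfig:
    return AnalysisConfig(**cfg.get("analysis", {}))


def read_trace_csv(path: str | Path) -> FluorescenceTrace:
    df = pd.read_csv(path)
    if not {"time_s", "fluorescence_au"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns time_s, fluorescence_au")
    times = df["time_s"].to_numpy(dtype=float)
    dt = np.diff(times)
    if dt.size == 0:
        raise ValueError(f"{path}: empty trace")
    frame_period = float(np.median(dt))
    # snap to an exactly uniform grid; acquisition clocks are uniform but
    # CSV round-tripping is not
    times = times[0] + np.arange(times.size) * frame_period
    return FluorescenceTrace(times=times, values=df["fluorescence_au"].to_numpy(dtype=float), frame_period=frame_period)


def write_trace_csv(trace: FluorescenceTrace, path: str | Path) -> None:
    pd.DataFrame({"time_s": trace.times, "fluorescence_au": trace.values}).to_csv(path, index=False)


def read_labels_csv(path: str | Path) -> dict[str, float]:
    df = pd.read_csv(path)
    if not {"trial_id", "temperature"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns trial_id, temperature")
    return {str(r.trial_id): float(r.temperature) for r in df.itertuples()}
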