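"""End-to-end pipeline: traces -> detection distances -> group tables -> stats.

The detection distance (DD) of a trial is reconstructed by mapping each
transient's onset time back through the stimulus trajectory: the glyph's
lateral track position at onset gives one leg of the eye–screen right
triangle, and the hypotenuse is the eye-to-stimulus distance at the moment
the tectum first responded.  Onsets falling on receding legs or dwells are
excluded from DD (the stimulus was not approaching) but retained for the
shape metrics.

The statistical unit defaults to the peak level: every retained peak of
every trial contributes one DD/duration/FWHM value (and every adjacent
retained pair one inter-peak interval), with the per-trial mean also
reported.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from . import peaks as pk
from .geometry import EyeGeometry, Phase, StimulusKinematics, distance_bounds, distance_from_lateral, phase_at
from .peaks import ArtifactRules, FluorescenceTrace, Peak
from .stats import GroupData, StatsReport, analyze_parameter

__all__ = [
    "AnalysisConfig",
    "TrialResult",
    "detection_distance_for_peak",
    "summarize_trial",
    "analyze_trial",
    "run_experiment",
    "PARAMETERS",
]

PARAMETERS = ("detection_distance", "duration", "fwhm", "inter_peak_interval", "fmax_fbase")


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable knobs of the trace-to-table pipeline."""

    min_prominence: float | None = None  # None -> 5 * sigma_noise
    min_separation_s: float = 1.0
    k_onset: float = 2.0
    merge_window_s: float = 1.0
    max_peaks: int = 5  # first-N rule
    dd_policy: Literal["mean", "first", "max"] = "mean"
    stat_unit: Literal["peak", "trial"] = "peak"
    posthoc_assignment: Literal["conventional", "as_published"] = "conventional"
    dunn_adjust: Literal["bonferroni", "none", "sidak"] = "bonferroni"
    alpha: float = 0.05


def detection_distance_for_peak(peak: Peak, kin: StimulusKinematics, geo: EyeGeometry) -> float | None:
    """Eye-to-stimulus distance at the peak's onset, or None off-approach.

    Raises ``ValueError`` for onsets before stimulus motion (those should
    have been artifact-flagged upstream).
    """
    phase, x = phase_at(peak.t_onset, kin)
    if phase is Phase.PRE:
        raise ValueError("peak onset precedes stimulus motion; flag as artifact upstream")
    if phase is not Phase.APPROACH:
        return None
    return distance_from_lateral(x, geo)


@dataclass
class TrialResult:
    """Per-trial detection distances and peak-shape metrics."""

    trial_id: str
    temperature: float | None
    status: str  # "ok" | "no_peaks"
    detection_distances: list[float] = field(default_factory=list)
    dd_summary: float = float("nan")
    durations: list[float] = field(default_factory=list)
    fwhms: list[float] = field(default_factory=list)
    intervals: list[float] = field(default_factory=list)
    fmax_fbase: list[float] = field(default_factory=list)
    n_detected: int = 0
    n_retained: int = 0


def _dd_summary(dds: list[float], policy: str) -> float:
    if not dds:
        return float("nan")
    if policy == "first":
        return dds[0]
    if policy == "max":
        return max(dds)
    return float(np.mean(dds))


def summarize_trial(
    peaks: Sequence[Peak],
    kin: StimulusKinematics,
    geo: EyeGeometry,
    trace: FluorescenceTrace,
    config: AnalysisConfig = AnalysisConfig(),
    trial_id: str = "",
    temperature: float | None = None,
) -> TrialResult:
    """Apply the retention pipeline and compute per-trial metrics.

    Order: artifact flagging -> double-top merging -> first-five selection;
    then per-peak DD (approach-leg onsets only) and shape metrics.
    """
    rules = ArtifactRules(t_move_start=kin.t_move_start)
    flagged = pk.flag_artifacts(list(peaks), trace, rules)
    merged = pk.merge_double_tops(flagged, trace, merge_window=config.merge_window_s)
    retained = pk.select_first_n(merged, n=config.max_peaks)
    if not retained:
        return TrialResult(trial_id=trial_id, temperature=temperature, status="no_peaks", n_detected=len(peaks))

    dmin, dmax = distance_bounds(kin, geo)
    dds = []
    for p in retained:
        dd = detection_distance_for_peak(p, kin, geo)
        if dd is None:
            continue
        if not (dmin - 1e-9 <= dd <= dmax + 1e-9):
            raise AssertionError(f"detection distance {dd} outside attainable range [{dmin}, {dmax}]")
        dds.append(dd)
    return TrialResult(
        trial_id=trial_id,
        temperature=temperature,
        status="ok",
        detection_distances=dds,
        dd_summary=_dd_summary(dds, config.dd_policy),
        durations=[pk.duration(p) for p in retained],
        fwhms=[p.fwhm for p in retained if np.isfinite(p.fwhm)],
        intervals=pk.inter_peak_intervals(retained),
        fmax_fbase=[pk.fmax_fbase(p) for p in retained],
        n_detected=len(peaks),
        n_retained=len(retained),
    )


def analyze_trial(
    trace: FluorescenceTrace,
    kin: StimulusKinematics,
    geo: EyeGeometry,
    config: AnalysisConfig = AnalysisConfig(),
    trial_id: str = "",
    temperature: float | None = None,
) -> TrialResult:
    """Detect peaks in a raw trace and summarize the trial."""
    detected = pk.detect_peaks(
        trace,
        min_prominence=config.min_prominence,
        min_separation=config.min_separation_s,
        k_onset=config.k_onset,
    )
    return summarize_trial(detected, kin, geo, trace, config, trial_id=trial_id, temperature=temperature)


def _long_table(results: Iterable[TrialResult], stat_unit: str) -> pd.DataFrame:
    rows = []
    for r in results:
        if r.status != "ok":
            continue
        per_param = {
            "detection_distance": r.detection_distances,
            "duration": r.durations,
            "fwhm": r.fwhms,
            "inter_peak_interval": r.intervals,
            "fmax_fbase": r.fmax_fbase,
        }
        for param, vals in per_param.items():
            if stat_unit == "trial":
                vals = [float(np.mean(vals))] if vals else []
            for v in vals:
                rows.append({"trial_id": r.trial_id, "temperature": r.temperature, "parameter": param, "value": float(v)})
    return pd.DataFrame(rows, columns=["trial_id", "temperature", "parameter", "value"])


def run_experiment(
    trials: Sequence[tuple[str, float, FluorescenceTrace]],
    kin: StimulusKinematics = StimulusKinematics(),
    geo: EyeGeometry = EyeGeometry(),
    config: AnalysisConfig = AnalysisConfig(),
) -> tuple[pd.DataFrame, dict]:
    """Analyze labeled trials and compare parameters across temperatures.

    ``trials`` is a sequence of ``(trial_id, temperature, trace)``.  Returns
    the tidy long-format table (trial, temperature, parameter, value) and a
    JSON-serialisable stats report.  Deterministic given its inputs.
    """
    for t in trials:
        if t[1] is None:
            raise ValueError(f"trial {t[0]!r} is missing its temperature label")
    results = [
        analyze_trial(trace, kin, geo, config, trial_id=tid, temperature=temp)
        for tid, temp, trace in trials
    ]
    table = _long_table(results, config.stat_unit)
    temperatures = sorted({r.temperature for r in results if r.status == "ok"})
    report: dict = {
        "schema_version": 1,
        "n_trials": len(results),
        "n_ok": sum(r.status == "ok" for r in results),
        "stat_unit": config.stat_unit,
        "group_means": {},
        "parameters": {},
    }
    for param in PARAMETERS:
        sub = table[table["parameter"] == param]
        by_temp = {t: sub.loc[sub["temperature"] == t, "value"].to_numpy() for t in temperatures}
        by_temp = {t: v for t, v in by_temp.items() if v.size >= 2}
        report["group_means"][param] = {str(t): float(np.mean(v)) for t, v in by_temp.items()}
        if len(by_temp) < 2:
            report["parameters"][param] = {"status": "skipped", "reason": "fewer than two groups with >= 2 values"}
            continue
        groups = GroupData.from_mapping(by_temp)
        try:
            rep = analyze_parameter(
                groups,
                parameter=param,
                alpha=config.alpha,
                posthoc_assignment=config.posthoc_assignment,
                dunn_adjust=config.dunn_adjust,
            )
        except ValueError as exc:
            report["parameters"][param] = {"status": "skipped", "reason": str(exc)}
            continue
        report["parameters"][param] = {"status": "ok", **rep.to_dict()}
    return table, report


def report_to_json(report: dict) -> str:
    """Canonical JSON serialisation (stable byte output for fixed inputs)."""
    return json.dumps(report, indent=2, sort_keys=True)
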