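"""Transient detection and peak-shape metrics for ROI fluorescence traces.

Given a uniformly sampled ROI-mean fluorescence trace, this module finds the
calcium transients evoked by the approaching stimulus and measures the four
response parameters used downstream:

* onset/offset and hence **duration** of each transient,
* **FWHM** — full width at half the amplitude above baseline,
* **inter-peak interval** — offset of one transient to onset of the next,
* **F_max/F_base** — transient maximum over inter-transient baseline.

Detection is a two-pass scheme.  A provisional baseline (rolling low
percentile) and robust noise level (scaled MAD) locate candidate maxima via
topographic prominence; onset and offset are the threshold crossings of
``f_base + k * sigma_noise`` nearest the maximum (linearly interpolated).
The final baseline is the median of all samples outside the detected
transients, and crossings are re-derived against it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage, signal

__all__ = [
    "FluorescenceTrace",
    "Peak",
    "ArtifactRules",
    "DegenerateInputError",
    "estimate_baseline",
    "robust_noise_sd",
    "detect_peaks",
    "merge_double_tops",
    "flag_artifacts",
    "select_first_n",
    "fwhm",
    "duration",
    "inter_peak_intervals",
    "fmax_fbase",
]

_UNIFORMITY_TOL_S = 1e-9


class DegenerateInputError(ValueError):
    """Raised when a trace or peak does not admit the requested measurement."""


@dataclass
class FluorescenceTrace:
    """Uniformly sampled ROI-mean fluorescence versus time.

    ``times`` are in seconds (strictly increasing, uniform), ``values`` in
    arbitrary fluorescence units, ``frame_period`` in seconds.
    """

    times: np.ndarray
    values: np.ndarray
    frame_period: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise ValueError("times and values must be matching 1-D arrays")
        if self.times.size < 10:
            raise ValueError("trace must contain at least 10 samples")
        dt = np.diff(self.times)
        if np.any(dt <= 0):
            raise ValueError("times must be strictly increasing")
        if np.max(np.abs(dt - self.frame_period)) > _UNIFORMITY_TOL_S:
            raise ValueError("times must be uniform at frame_period")

    @classmethod
    def from_values(cls, values: np.ndarray, frame_period: float, t0: float = 0.0) -> "FluorescenceTrace":
        values = np.asarray(values, dtype=float)
        times = t0 + np.arange(values.size) * frame_period
        return cls(times=times, values=values, frame_period=frame_period)

    @property
    def n_frames(self) -> int:
        return int(self.times.size)


@dataclass
class Peak:
    """One detected calcium transient."""

    t_onset: float
    t_max: float
    t_offset: float
    f_max: float
    f_base: float
    duration: float = field(init=False)
    fwhm: float = float("nan")
    is_artifact: bool = False
    merged_from: int = 1

    def __post_init__(self) -> None:
        if not (self.t_onset < self.t_max < self.t_offset):
            raise ValueError("peak requires t_onset < t_max < t_offset")
        if not self.f_max > self.f_base:
            raise ValueError("peak requires f_max > f_base")
        self.duration = self.t_offset - self.t_onset


def robust_noise_sd(samples: np.ndarray) -> float:
    """Robust noise SD via 1.4826 * median absolute deviation."""
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise DegenerateInputError("no samples for noise estimation")
    return 1.4826 * float(np.median(np.abs(samples - np.median(samples))))


def _rolling_low_percentile(values: np.ndarray, frame_period: float, window_s: float, percentile: float) -> np.ndarray:
    size = max(3, int(round(window_s / frame_period)) | 1)
    size = min(size, values.size)
    return ndimage.percentile_filter(values, percentile, size=size, mode="nearest")


def estimate_baseline(trace: FluorescenceTrace, peak_regions: list[tuple[float, float]]) -> float:
    """Baseline fluorescence: median of samples outside all transients.

    ``peak_regions`` are (t_onset, t_offset) windows to exclude.  Raises
    :class:`DegenerateInputError` when no inter-transient sample remains.
    """
    mask = np.ones(trace.n_frames, dtype=bool)
    for t0, t1 in peak_regions:
        mask &= ~((trace.times >= t0) & (trace.times <= t1))
    if not mask.any():
        raise DegenerateInputError("no inter-peak samples available for the baseline")
    return float(np.median(trace.values[mask]))


def _interp_crossing(t0: float, v0: float, t1: float, v1: float, level: float) -> float:
    if v1 == v0:
        return t0
    return t0 + (level - v0) * (t1 - t0) / (v1 - v0)


def _onset_offset(
    trace: FluorescenceTrace,
    idx_max: int,
    level: float,
    lo_bound: int,
    hi_bound: int,
) -> tuple[float, float]:
    """Threshold crossings nearest the maximum, searched within bounds.

    ``lo_bound``/``hi_bound`` confine the search between neighbouring maxima;
    when the trace never returns to the threshold within the window the
    boundary sample (the valley towards the neighbour, or the trace edge) is
    used, which keeps adjacent transients non-overlapping.
    """
    t, v = trace.times, trace.values
    # onset: last sample at/below the level before the maximum
    onset = None
    for j in range(idx_max - 1, lo_bound - 1, -1):
        if v[j] <= level:
            onset = _interp_crossing(t[j], v[j], t[j + 1], v[j + 1], level)
            break
    if onset is None:
        onset = t[lo_bound]
    offset = None
    for j in range(idx_max + 1, hi_bound + 1):
        if v[j] <= level:
            offset = _interp_crossing(t[j - 1], v[j - 1], t[j], v[j], level)
            break
    if offset is None:
        offset = t[hi_bound]
    return float(onset), float(offset)


def _valley_bounds(values: np.ndarray, maxima: np.ndarray) -> list[tuple[int, int]]:
    """Per-maximum search bounds: the minima between adjacent maxima."""
    bounds = []
    n = values.size
    for i, m in enumerate(maxima):
        lo = 0 if i == 0 else maxima[i - 1] + int(np.argmin(values[maxima[i - 1] : m + 1]))
        hi = n - 1 if i == len(maxima) - 1 else m + int(np.argmin(values[m : maxima[i + 1] + 1]))
        bounds.append((lo, hi))
    return bounds


def detect_peaks(
    trace: FluorescenceTrace,
    min_prominence: float | None = None,
    min_separation: float = 1.0,
    k_onset: float = 2.0,
    baseline_window_s: float = 15.0,
    baseline_percentile: float = 20.0,
) -> list[Peak]:
    """Detect calcium transients in ``trace``.

    Maxima are local peaks with topographic prominence >= ``min_prominence``
    (default ``5 * sigma_noise``) separated by >= ``min_separation`` s.
    Onset/offset are crossings of ``f_base + k_onset * sigma_noise`` with
    linear interpolation between frames; ``sigma_noise`` is 1.4826 x MAD of
    the inter-transient samples.  Returns peaks sorted by onset; an empty
    list for a flat trace.
    """
    v = trace.values
    fp = trace.frame_period

    # pass 1: provisional baseline and noise from a rolling low percentile
    b0 = _rolling_low_percentile(v, fp, baseline_window_s, baseline_percentile)
    resid = v - b0
    sigma0 = robust_noise_sd(resid)
    span = float(np.max(v) - np.min(v))
    if span == 0.0:
        return []
    prominence = min_prominence if min_prominence is not None else max(5.0 * sigma0, 1e-12 * max(1.0, abs(float(np.max(v)))))
    distance = max(1, int(round(min_separation / fp)))
    maxima, _ = signal.find_peaks(v, prominence=prominence, distance=distance)
    if maxima.size == 0:
        return []

    below = v <= b0 + 2.0 * sigma0
    f_base1 = float(np.median(v[below])) if below.any() else float(np.median(b0))
    bounds = _valley_bounds(v, maxima)

    level1 = f_base1 + k_onset * sigma0
    regions = []
    for m, (lo, hi) in zip(maxima, bounds):
        on, off = _onset_offset(trace, m, level1, lo, hi)
        regions.append((on, off))

    # pass 2: final baseline/noise from samples outside the provisional transients
    mask = np.ones(trace.n_frames, dtype=bool)
    for t0, t1 in regions:
        mask &= ~((trace.times >= t0) & (trace.times <= t1))
    if mask.any():
        f_base = float(np.median(v[mask]))
        sigma = robust_noise_sd(v[mask])
    else:
        f_base, sigma = f_base1, sigma0

    level = f_base + k_onset * sigma
    peaks: list[Peak] = []
    for m, (lo, hi) in zip(maxima, bounds):
        on, off = _onset_offset(trace, m, level, lo, hi)
        f_max = float(v[m])
        if not (on < trace.times[m] < off) or f_max <= f_base:
            continue  # maximum swallowed by the threshold (noise blip)
        pk = Peak(t_onset=on, t_max=float(trace.times[m]), t_offset=off, f_max=f_max, f_base=f_base)
        try:
            pk.fwhm = fwhm(pk, trace)
        except DegenerateInputError:
            pk.fwhm = float("nan")
        peaks.append(pk)
    peaks.sort(key=lambda p: p.t_onset)
    return peaks


def fwhm(peak: Peak, trace: FluorescenceTrace) -> float:
    """Full width at half maximum of ``peak`` in seconds.

    The half level is ``f_base + (f_max - f_base) / 2`` — amplitude measured
    above baseline.  Crossings nearest ``t_max`` are linearly interpolated
    and must be bracketed within ``[t_onset, t_offset]``.
    """
    half = peak.f_base + (peak.f_max - peak.f_base) / 2.0
    t, v = trace.times, trace.values
    # include the grid samples bracketing the interpolated onset/offset
    lo = max(0, int(np.searchsorted(t, peak.t_onset, side="right")) - 1)
    hi = min(t.size - 1, int(np.searchsorted(t, peak.t_offset, side="left")))
    m = lo + int(np.argmax(v[lo : hi + 1]))
    left = None
    for j in range(m - 1, lo - 1, -1):
        if v[j] <= half:
            left = _interp_crossing(t[j], v[j], t[j + 1], v[j + 1], half)
            break
    right = None
    for j in range(m + 1, hi + 1):
        if v[j] <= half:
            right = _interp_crossing(t[j - 1], v[j - 1], t[j], v[j], half)
            break
    if left is None or right is None:
        raise DegenerateInputError("half-maximum crossing not bracketed within the peak")
    # the extra bracketing sample can push a crossing marginally outside the
    # onset/offset window; clamp so fwhm <= duration holds exactly
    left = max(left, peak.t_onset)
    right = min(right, peak.t_offset)
    return float(right - left)


def merge_double_tops(peaks: list[Peak], trace: FluorescenceTrace, merge_window: float = 1.0) -> list[Peak]:
    """Merge double-topped transients into single peaks.

    Adjacent maxima closer than ``merge_window`` s whose intervening minimum
    stays above half of the lower maximum's amplitude (above base) are one
    physiological transient recorded with a dip; they are merged into a
    single :class:`Peak` spanning both.  Idempotent.
    """
    peaks = sorted(peaks, key=lambda p: p.t_onset)
    changed = True
    while changed:
        changed = False
        out: list[Peak] = []
        i = 0
        while i < len(peaks):
            p = peaks[i]
            if i + 1 < len(peaks):
                q = peaks[i + 1]
                gap = q.t_max - p.t_max
                if gap < merge_window and _valley_above_half(p, q, trace):
                    merged = Peak(
                        t_onset=p.t_onset,
                        t_max=p.t_max if p.f_max >= q.f_max else q.t_max,
                        t_offset=q.t_offset,
                        f_max=max(p.f_max, q.f_max),
                        f_base=p.f_base,
                        merged_from=p.merged_from + q.merged_from,
                    )
                    merged.is_artifact = p.is_artifact and q.is_artifact
                    try:
                        merged.fwhm = fwhm(merged, trace)
                    except DegenerateInputError:
                        merged.fwhm = float("nan")
                    out.append(merged)
                    i += 2
                    changed = True
                    continue
            out.append(p)
            i += 1
        peaks = out
    return peaks


def _valley_above_half(p: Peak, q: Peak, trace: FluorescenceTrace) -> bool:
    sel = (trace.times >= p.t_max) & (trace.times <= q.t_max)
    if not sel.any():
        return False
    valley = float(np.min(trace.values[sel]))
    lower_amp = min(p.f_max, q.f_max) - p.f_base
    return valley - p.f_base > 0.5 * lower_amp


@dataclass(frozen=True)
class ArtifactRules:
    """Switchable exclusion rules for non-physiological peaks."""

    min_duration_frames: int | None = 2  # shorter-than-this transients are artifacts
    spike_factor: float | None = 5.0  # f_max amplitude > factor x median amplitude
    t_move_start: float | None = None  # onsets before stimulus motion are artifacts


def flag_artifacts(peaks: list[Peak], trace: FluorescenceTrace, rules: ArtifactRules = ArtifactRules()) -> list[Peak]:
    """Return peaks with ``is_artifact`` set per the enabled rules.

    Rules (each individually switchable via ``None``): implausibly short
    duration; amplitude spikes far above the trace's own robust amplitude
    scale; onsets preceding stimulus motion.
    """
    amps = np.array([p.f_max - p.f_base for p in peaks])
    median_amp = float(np.median(amps)) if amps.size >= 3 else None
    out = []
    for p in peaks:
        flagged = p.is_artifact
        if rules.min_duration_frames is not None:
            if p.duration < rules.min_duration_frames * trace.frame_period:
                flagged = True
        if rules.spike_factor is not None and median_amp is not None and median_amp > 0:
            if (p.f_max - p.f_base) > rules.spike_factor * median_amp:
                flagged = True
        if rules.t_move_start is not None and p.t_onset < rules.t_move_start:
            flagged = True
        out.append(replace(p, is_artifact=flagged))
    return out


def select_first_n(peaks: list[Peak], n: int = 5) -> list[Peak]:
    """First ``n`` non-artifact peaks by onset time (the analysis window)."""
    kept = [p for p in sorted(peaks, key=lambda p: p.t_onset) if not p.is_artifact]
    return kept[:n]


def duration(peak: Peak) -> float:
    """Transient duration in s (offset minus onset)."""
    return peak.duration


def inter_peak_intervals(peaks: list[Peak]) -> list[float]:
    """Offset-to-next-onset gaps in s (length ``len(peaks) - 1``)."""
    peaks = sorted(peaks, key=lambda p: p.t_onset)
    out = []
    for a, b in zip(peaks, peaks[1:]):
        gap = b.t_onset - a.t_offset
        if gap < -1e-9:
            raise RuntimeError("overlapping peaks after merging — internal error")
        out.append(max(0.0, gap))
    return out


def fmax_fbase(peak: Peak) -> float:
    """Ratio of maximum to baseline fluorescence."""
    return peak.f_max / peak.f_base
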