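"""Synthetic GCaMP-like recordings with known ground truth.

Emulates the study conditions: a larva views a cross-shaped glyph shuttling
along a 6.3 mm track at 2.1 mm/s for 10 cycles, and each approach leg evokes
one calcium transient in the optic tectum once the glyph comes within the
fish's (unknown, to-be-estimated) detection distance.  Traces are sampled at
the acquisition frame period of 50 ms (20 ms exposure + 30 ms gap).

The transient impulse response is a double-exponential indicator kernel

    k(t) = A' * (1 - exp(-t / tau_rise)) * exp(-t / tau_decay),  t >= 0

normalised so its maximum equals the requested peak ``amplitude`` (as a
fractional change over baseline).  The peak time is the closed form
``tau_rise * log(1 + tau_decay / tau_rise)``.

Noise is additive Gaussian on the fluorescence; shot noise and bleaching are
deliberately out of scope (see the methods note).  Every stochastic output
is reproducible from its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .geometry import EyeGeometry, StimulusKinematics, distance_bounds, first_time_within
from .peaks import FluorescenceTrace
from .roi import RingROI, ring_mask

__all__ = [
    "KernelParams",
    "SyntheticTruth",
    "TreatmentSpec",
    "TemperatureEffectModel",
    "SyntheticTrial",
    "gcamp_kernel",
    "kernel_peak_time",
    "simulate_trial",
    "simulate_experiment",
    "render_stack",
    "DEFAULT_FRAME_PERIOD_S",
]

# 20 ms exposure + 30 ms inter-exposure gap
DEFAULT_FRAME_PERIOD_S = 0.05
# acquisition continues this long after the last stimulus cycle
POST_STIMULUS_S = 30.0


@dataclass(frozen=True)
class KernelParams:
    """Double-exponential indicator impulse response."""

    tau_rise: float = 0.05  # s
    tau_decay: float = 0.7  # s
    amplitude: float = 0.2  # peak dF/F over baseline

    def __post_init__(self) -> None:
        if not 0 < self.tau_rise < self.tau_decay:
            raise ValueError("require 0 < tau_rise < tau_decay")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")


def kernel_peak_time(k: KernelParams) -> float:
    """Closed-form time of the kernel maximum: tau_r * ln(1 + tau_d/tau_r)."""
    return k.tau_rise * math.log(1.0 + k.tau_decay / k.tau_rise)


def gcamp_kernel(t: np.ndarray | float, k: KernelParams) -> np.ndarray | float:
    """Kernel value(s) at time(s) ``t`` (s after the event); 0 for t < 0."""
    t_arr = np.asarray(t, dtype=float)
    t_star = kernel_peak_time(k)
    norm = (1.0 - math.exp(-t_star / k.tau_rise)) * math.exp(-t_star / k.tau_decay)
    out = np.where(
        t_arr >= 0,
        (k.amplitude / norm)
        * (1.0 - np.exp(-np.clip(t_arr, 0, None) / k.tau_rise))
        * np.exp(-np.clip(t_arr, 0, None) / k.tau_decay),
        0.0,
    )
    return float(out) if np.isscalar(t) else out


@dataclass
class SyntheticTruth:
    """Ground truth for one simulated trial."""

    dd_true: float  # mm, detection distance
    kernel: KernelParams = KernelParams()
    latency: float = 0.0  # s, detection-to-fluorescence delay
    noise_sd: float = 0.02  # relative fluorescence (fraction of baseline)
    f_base_true: float = 100.0  # a.u.
    event_times: list[float] | None = None  # filled by the simulator

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.f_base_true <= 0:
            raise ValueError("f_base_true must be positive")
        if self.latency < 0:
            raise ValueError("latency must be >= 0")


def simulate_trial(
    truth: SyntheticTruth,
    kin: StimulusKinematics,
    geo: EyeGeometry,
    frame_period: float = DEFAULT_FRAME_PERIOD_S,
    n_frames: int | None = None,
    seed: int | None = None,
) -> tuple[FluorescenceTrace, list[float]]:
    """Simulate one trial's ROI trace.

    One transient fires per approach leg at ``first_time_within(dd_true) +
    latency``; legs on which ``dd_true`` is unattainable are silent.  The
    trace is ``f_base * (1 + sum of kernels) + N(0, noise_sd * f_base)``.
    Returns the trace and the ground-truth event times.
    """
    dmin, dmax = distance_bounds(kin, geo)
    if truth.dd_true < dmin:
        raise ValueError(f"dd_true={truth.dd_true} below minimum attainable distance {dmin}")
    events: list[float] = []
    for c in range(kin.n_cycles):
        try:
            events.append(first_time_within(truth.dd_true, kin, geo, cycle=c) + truth.latency)
        except ValueError:
            continue
    if not events:
        raise ValueError("dd_true is unattainable on every approach leg")
    if n_frames is None:
        n_frames = int(math.ceil((kin.t_move_end + POST_STIMULUS_S) / frame_period)) + 1
    times = np.arange(n_frames) * frame_period
    signal = np.zeros(n_frames)
    for te in events:
        signal += gcamp_kernel(times - te, truth.kernel)
    values = truth.f_base_true * (1.0 + signal)
    if truth.noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, truth.noise_sd * truth.f_base_true, size=n_frames)
    truth.event_times = events
    return FluorescenceTrace(times=times, values=values, frame_period=frame_period), events


@dataclass(frozen=True)
class TreatmentSpec:
    """Per-temperature generator parameters."""

    temperature: float  # degrees C
    dd_mean: float  # mm
    dd_sd: float  # mm
    tau_decay_mean: float  # s
    duration_scale: float = 1.0  # multiplies both kernel time constants
    amplitude: float = 0.2  # peak dF/F
    noise_sd: float = 0.02  # relative fluorescence

    def __post_init__(self) -> None:
        if self.dd_sd < 0 or self.noise_sd < 0:
            raise ValueError("standard deviations must be >= 0")


def _default_treatments() -> tuple[TreatmentSpec, ...]:
    # Colder fish detect the stimulus farther away, with slower (wider)
    # transients; amplitudes put F_max/F_base in the 1.15-1.25 range.
    return (
        TreatmentSpec(temperature=18.0, dd_mean=5.5, dd_sd=0.6, tau_decay_mean=1.4, amplitude=0.25),
        TreatmentSpec(temperature=23.0, dd_mean=4.8, dd_sd=0.6, tau_decay_mean=1.0, amplitude=0.16),
        TreatmentSpec(temperature=28.0, dd_mean=3.5, dd_sd=0.6, tau_decay_mean=0.7, amplitude=0.15),
    )


@dataclass(frozen=True)
class TemperatureEffectModel:
    """Three-treatment generative model of the temperature effect."""

    treatments: tuple[TreatmentSpec, ...] = field(default_factory=_default_treatments)
    tau_rise: float = 0.05  # s, shared rise time constant
    f_base_true: float = 100.0  # a.u.

    def __post_init__(self) -> None:
        if len(self.treatments) < 2:
            raise ValueError("need at least two treatments")


@dataclass
class SyntheticTrial:
    """One labeled simulated trial."""

    trial_id: str
    temperature: float
    trace: FluorescenceTrace
    truth: SyntheticTruth


def _truncnorm_draw(mean: float, sd: float, lo: float, hi: float, rng: np.random.Generator) -> float:
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(sps.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def simulate_experiment(
    model: TemperatureEffectModel = TemperatureEffectModel(),
    n_fish_per_temp: int = 20,
    seed: int | None = None,
    kin: StimulusKinematics = StimulusKinematics(),
    geo: EyeGeometry = EyeGeometry(),
    frame_period: float = DEFAULT_FRAME_PERIOD_S,
) -> tuple[list[SyntheticTrial], pd.DataFrame]:
    """Simulate a full three-temperature experiment.

    Per-fish detection distances are drawn from each treatment's Normal,
    truncated to the geometrically attainable range.  Returns the labeled
    trials and a tidy ground-truth table; fully reproducible from ``seed``.
    """
    if n_fish_per_temp < 2:
        raise ValueError("need at least 2 fish per treatment")
    rng = np.random.default_rng(seed)
    dmin, dmax = distance_bounds(kin, geo)
    trials: list[SyntheticTrial] = []
    rows = []
    for spec in model.treatments:
        for i in range(n_fish_per_temp):
            dd = _truncnorm_draw(spec.dd_mean, spec.dd_sd, dmin, dmax, rng)
            kernel = KernelParams(
                tau_rise=model.tau_rise * spec.duration_scale,
                tau_decay=spec.tau_decay_mean * spec.duration_scale,
                amplitude=spec.amplitude,
            )
            truth = SyntheticTruth(
                dd_true=dd,
                kernel=kernel,
                noise_sd=spec.noise_sd,
                f_base_true=model.f_base_true,
            )
            trial_seed = int(rng.integers(0, 2**31 - 1))
            trace, events = simulate_trial(truth, kin, geo, frame_period=frame_period, seed=trial_seed)
            trial_id = f"T{spec.temperature:g}_{i:02d}"
            trials.append(SyntheticTrial(trial_id=trial_id, temperature=spec.temperature, trace=trace, truth=truth))
            rows.append(
                {
                    "trial_id": trial_id,
                    "temperature": spec.temperature,
                    "dd_true": dd,
                    "tau_rise": kernel.tau_rise,
                    "tau_decay": kernel.tau_decay,
                    "amplitude": kernel.amplitude,
                    "noise_sd": spec.noise_sd,
                    "n_events": len(events),
                    "first_event_s": events[0],
                }
            )
    return trials, pd.DataFrame(rows)


def render_stack(
    trace: FluorescenceTrace,
    image_shape: tuple[int, int],
    roi_center: tuple[float, float],
    roi_diameter_um: float,
    pixel_size_um: float,
    background: float = 0.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
    thickness_px: float = 1.0,
) -> np.ndarray:
    """Render the trace into a synthetic image stack with a bright ring.

    Pixels on the ring annulus carry the trace value for that frame; all
    other pixels carry ``background``; optional Gaussian read noise on top.
    Round-trips exactly through ring-ROI extraction at zero noise.
    """
    roi = RingROI(center=roi_center, diameter_um=roi_diameter_um, pixel_size_um=pixel_size_um, thickness_px=thickness_px)
    mask = ring_mask(roi, image_shape)  # validates bounds
    n = trace.n_frames
    stack = np.full((n, *image_shape), float(background))
    stack[:, mask] = trace.values[:, None]
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        stack = stack + rng.normal(0.0, noise_sd, size=stack.shape)
    return stack
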