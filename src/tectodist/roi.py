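"""Ring-shaped ROI extraction from time-lapse image stacks.

The recorded region of interest is a thin ring (default 10 um outer
diameter) placed over the tectal neuropil location that responds first to
the approaching stimulus.  The trace is the per-frame mean over the ring
pixels; ROI placement is an exhaustive search maximising the F_max/F_base
response score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from .peaks import DegenerateInputError, FluorescenceTrace, robust_noise_sd

__all__ = ["RingROI", "ScoredROI", "ring_mask", "extract_trace", "select_roi", "response_score"]


@dataclass(frozen=True)
class RingROI:
    """A 1-pixel-thick (by default) annulus ROI.

    ``center`` is (row, col) in pixels; ``diameter_um`` is the outer ring
    diameter in micrometres, converted to pixels via ``pixel_size_um``.
    """

    center: tuple[float, float]
    diameter_um: float = 10.0
    pixel_size_um: float = 0.457
    thickness_px: float = 1.0

    def __post_init__(self) -> None:
        if self.diameter_um <= 0 or self.pixel_size_um <= 0 or self.thickness_px <= 0:
            raise ValueError("diameter, pixel size and thickness must be positive")

    @property
    def radius_px(self) -> float:
        return self.diameter_um / (2.0 * self.pixel_size_um)


class ScoredROI(NamedTuple):
    roi: RingROI
    score: float


def ring_mask(roi: RingROI, image_shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of pixels whose centre lies on the annulus.

    A pixel belongs to the ring when its centre distance from ``roi.center``
    is within ``[r - thickness/2, r + thickness/2]``.
    """
    r = roi.radius_px
    half = roi.thickness_px / 2.0
    cr, cc = roi.center
    if cr - r - half < -0.5 or cc - r - half < -0.5 or cr + r + half > image_shape[0] - 0.5 or cc + r + half > image_shape[1] - 0.5:
        raise ValueError("ring extends outside the image")
    rows = np.arange(image_shape[0])[:, None]
    cols = np.arange(image_shape[1])[None, :]
    dist = np.hypot(rows - cr, cols - cc)
    mask = (dist >= r - half) & (dist <= r + half)
    if mask.sum() < 4:
        raise ValueError("ring contains fewer than 4 pixels")
    return mask


def extract_trace(stack: np.ndarray, roi: RingROI, frame_period: float = 0.05, t0: float = 0.0) -> FluorescenceTrace:
    """Per-frame mean fluorescence over the ring pixels."""
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3 or stack.shape[0] < 1:
        raise ValueError("stack must be (n_frames, rows, cols) with >= 1 frame")
    mask = ring_mask(roi, stack.shape[1:])
    values = stack[:, mask].mean(axis=1)
    return FluorescenceTrace.from_values(values, frame_period=frame_period, t0=t0)


def response_score(trace: FluorescenceTrace) -> float:
    """F_max/F_base score of a trace; baseline from the robust low side.

    Baseline is the median of samples within 2 robust SD of a rolling low
    percentile — the same provisional estimate peak detection starts from.
    """
    from .peaks import _rolling_low_percentile  # shared provisional-baseline pass

    v = trace.values
    b0 = _rolling_low_percentile(v, trace.frame_period, window_s=15.0, percentile=20.0)
    sigma = robust_noise_sd(v - b0)
    below = v <= b0 + 2.0 * sigma
    f_base = float(np.median(v[below])) if below.any() else float(np.median(b0))
    if f_base <= 0:
        raise DegenerateInputError("non-positive baseline; response score undefined")
    return float(np.max(v)) / f_base


def select_roi(
    stack: np.ndarray,
    candidate_centers: Sequence[tuple[float, float]],
    roi_template: RingROI,
    frame_period: float = 0.05,
) -> ScoredROI:
    """Place the ring at the candidate centre maximising F_max/F_base.

    Ties break deterministically towards the lexicographically smallest
    (row, col) centre.
    """
    if len(candidate_centers) == 0:
        raise ValueError("need at least one candidate centre")
    best: ScoredROI | None = None
    degenerate = 0
    for center in sorted(candidate_centers):
        roi = RingROI(
            center=tuple(center),
            diameter_um=roi_template.diameter_um,
            pixel_size_um=roi_template.pixel_size_um,
            thickness_px=roi_template.thickness_px,
        )
        try:
            score = response_score(extract_trace(stack, roi, frame_period=frame_period))
        except DegenerateInputError:
            degenerate += 1
            continue
        if best is None or score > best.score:
            best = ScoredROI(roi=roi, score=score)
    if best is None:
        raise DegenerateInputError("all candidate traces are degenerate (zero baseline)")
    return best
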