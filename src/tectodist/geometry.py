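"""Stimulus geometry: the moving-dot trajectory on the display and the eye–screen triangle.

The artificial prey is a small cross-shaped glyph on a miniature OLED display
mounted parallel to the long axis of the larva, 1 mm from the eye surface at
the closest point.  The glyph shuttles back and forth along a horizontal
track at constant speed, so the eye-to-stimulus distance is the hypotenuse of
a right triangle: one leg is the (fixed) eye–screen distance, the other the
lateral offset of the glyph from the point on the screen opposite the eye.

Conventions
-----------
* ``x`` is the lateral position along the track in mm, with ``x = 0`` at the
  track end nearest the closest-approach point.  By default the eye sits
  opposite ``x = 0`` (``eye_opposite_x = 0``) and the glyph starts at the far
  end of the track, so an *approach* leg is decreasing ``x``.
* Each stimulus cycle is approach → dwell → recede → dwell.  The dwell
  (motionless pause at the track ends) reconciles the nominal cycle period
  with the one-way travel time; by default it is split equally between the
  two ends.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

__all__ = [
    "ScreenSpec",
    "GlyphSpec",
    "StimulusKinematics",
    "EyeGeometry",
    "Phase",
    "pixel_speed",
    "lateral_position",
    "phase_at",
    "distance_from_lateral",
    "distance_at_time",
    "distance_bounds",
    "first_time_within",
    "glyph_extent",
    "angular_size",
    "angular_speed",
]


@dataclass(frozen=True)
class ScreenSpec:
    """Physical parameters of the monochrome OLED display."""

    n_cols: int = 64
    n_rows: int = 48
    pixel_pitch: float = 0.21  # mm, centre-to-centre
    dot_size: float = 0.19  # mm, lit area of one pixel
    contrast_ratio: float = 2000.0

    def __post_init__(self) -> None:
        if min(self.n_cols, self.n_rows) <= 0:
            raise ValueError("screen dimensions must be positive")
        if self.pixel_pitch <= 0 or self.dot_size <= 0 or self.contrast_ratio <= 0:
            raise ValueError("pitch, dot size and contrast must be positive")
        if self.dot_size > self.pixel_pitch:
            raise ValueError("dot_size cannot exceed pixel_pitch")


@dataclass(frozen=True)
class GlyphSpec:
    """The cross-shaped prey glyph (5 lit pixels spanning 3 pitches)."""

    n_pixels: int = 5
    extent_pitches: int = 3

    def __post_init__(self) -> None:
        if self.extent_pitches < 1 or self.extent_pitches % 2 == 0:
            raise ValueError("extent_pitches must be odd and >= 1")
        if self.n_pixels < 1:
            raise ValueError("n_pixels must be >= 1")


# Nominal trial timing: 10 shuttle cycles in 2 minutes.
_DEFAULT_CYCLE_PERIOD_S = 12.0


@dataclass(frozen=True)
class StimulusKinematics:
    """Triangular-wave trajectory of the glyph along the track.

    ``start_offset`` is the lateral position where the glyph sits before
    motion begins (default: the far end of the track).  ``dwell_per_cycle``
    is the total motionless time per cycle, split equally between the two
    track ends; the default is derived from a 12 s nominal cycle period
    (10 cycles in 2 min) minus the round-trip travel time.
    """

    speed: float = 2.1  # mm/s
    track_length: float = 6.3  # mm, one-way
    start_offset: float | None = None  # mm; None -> track_length
    n_cycles: int = 10
    t_move_start: float = 10.0  # s into the recording when motion begins
    dwell_per_cycle: float | None = None  # s; None -> derived

    def __post_init__(self) -> None:
        if self.speed <= 0 or self.track_length <= 0:
            raise ValueError("speed and track_length must be positive")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.t_move_start < 0:
            raise ValueError("t_move_start must be >= 0")
        if self.start_offset is None:
            object.__setattr__(self, "start_offset", self.track_length)
        if not 0.0 <= self.start_offset <= self.track_length:
            raise ValueError("start_offset must lie within [0, track_length]")
        if self.dwell_per_cycle is None:
            derived = max(0.0, _DEFAULT_CYCLE_PERIOD_S - 2.0 * self.track_length / self.speed)
            object.__setattr__(self, "dwell_per_cycle", derived)
        if self.dwell_per_cycle < 0:
            raise ValueError("dwell_per_cycle must be >= 0")

    @property
    def one_way_time(self) -> float:
        """Seconds to traverse the full track one way."""
        return self.track_length / self.speed

    @property
    def cycle_period(self) -> float:
        """Duration of one full (uniform) approach–recede cycle in s."""
        return 2.0 * self.one_way_time + self.dwell_per_cycle

    @property
    def first_cycle_duration(self) -> float:
        """Cycle 0 may be shorter when motion starts mid-track."""
        return self.start_offset / self.speed + self.one_way_time + self.dwell_per_cycle

    @property
    def t_move_end(self) -> float:
        """Time at which the last cycle (including trailing dwell) completes."""
        return self.t_move_start + self.first_cycle_duration + (self.n_cycles - 1) * self.cycle_period

    def approach_start(self, cycle: int) -> tuple[float, float]:
        """Return ``(t_start, x_start)`` of the approach leg of ``cycle``."""
        if not 0 <= cycle < self.n_cycles:
            raise ValueError(f"cycle must be in [0, {self.n_cycles})")
        if cycle == 0:
            return self.t_move_start, self.start_offset
        t = self.t_move_start + self.first_cycle_duration + (cycle - 1) * self.cycle_period
        return t, self.track_length


@dataclass(frozen=True)
class EyeGeometry:
    """Position of the eye relative to the screen plane."""

    eye_screen_distance: float = 1.0  # mm, perpendicular eye-to-screen distance
    eye_opposite_x: float = 0.0  # mm, lateral coordinate opposite the eye

    def __post_init__(self) -> None:
        if self.eye_screen_distance <= 0:
            raise ValueError("eye_screen_distance must be positive")


class Phase(str, enum.Enum):
    PRE = "pre"
    APPROACH = "approach"
    DWELL = "dwell"
    RECEDE = "recede"
    POST = "post"


def pixel_speed(pixel_pitch: float = 0.21, jump_interval: float = 0.1) -> float:
    """Glyph speed in mm/s from the pixel pitch and the per-pixel jump interval.

    The animation advances the glyph by one pixel pitch every ``jump_interval``
    seconds, which the analysis treats as continuous motion.
    """
    if pixel_pitch <= 0 or jump_interval <= 0:
        raise ValueError("pixel_pitch and jump_interval must be positive")
    return pixel_pitch / jump_interval


def phase_at(t: float, kin: StimulusKinematics) -> tuple[Phase, float]:
    """Classify time ``t`` and return ``(phase, lateral position in mm)``."""
    if t < 0:
        raise ValueError("t must be >= 0")
    if t < kin.t_move_start:
        return Phase.PRE, kin.start_offset
    tau = t - kin.t_move_start
    if tau < kin.first_cycle_duration:
        local = tau
        approach_time = kin.start_offset / kin.speed
        x_start = kin.start_offset
    else:
        tau2 = tau - kin.first_cycle_duration
        cycle = 1 + int(tau2 // kin.cycle_period)
        if cycle >= kin.n_cycles:
            return Phase.POST, kin.track_length
        local = tau2 - (cycle - 1) * kin.cycle_period
        approach_time = kin.one_way_time
        x_start = kin.track_length
    half_dwell = kin.dwell_per_cycle / 2.0
    if local < approach_time:
        return Phase.APPROACH, x_start - kin.speed * local
    local -= approach_time
    if local < half_dwell:
        return Phase.DWELL, 0.0
    local -= half_dwell
    if local < kin.one_way_time:
        return Phase.RECEDE, kin.speed * local
    return Phase.DWELL, kin.track_length


def lateral_position(t: float, kin: StimulusKinematics) -> float:
    """Lateral glyph position x(t) in mm along the track."""
    return phase_at(t, kin)[1]


def distance_from_lateral(x: float, geo: EyeGeometry) -> float:
    """Eye-to-glyph distance for lateral position ``x`` (Pythagoras)."""
    if x < 0:
        raise ValueError("x must be >= 0")
    return math.hypot(x - geo.eye_opposite_x, geo.eye_screen_distance)


def distance_at_time(t: float, kin: StimulusKinematics, geo: EyeGeometry) -> float:
    """Eye-to-glyph distance at time ``t`` in mm."""
    return distance_from_lateral(lateral_position(t, kin), geo)


def distance_bounds(kin: StimulusKinematics, geo: EyeGeometry) -> tuple[float, float]:
    """Attainable ``(min, max)`` eye-to-glyph distance over the track."""
    b = geo.eye_opposite_x
    if 0.0 <= b <= kin.track_length:
        dmin = geo.eye_screen_distance
    else:
        dmin = min(distance_from_lateral(0.0, geo), distance_from_lateral(kin.track_length, geo))
    dmax = max(distance_from_lateral(0.0, geo), distance_from_lateral(kin.track_length, geo))
    return dmin, dmax


def first_time_within(dd: float, kin: StimulusKinematics, geo: EyeGeometry, cycle: int = 0) -> float:
    """Earliest time on the approach leg of ``cycle`` at which the
    eye-to-glyph distance is <= ``dd`` mm.

    Analytic inversion of the piecewise-linear trajectory; no grid search.
    Raises ``ValueError`` when ``dd`` is not attainable on that leg.
    """
    dmin, dmax = distance_bounds(kin, geo)
    if dd < dmin - 1e-12:
        raise ValueError(f"dd={dd} below minimum attainable distance {dmin}")
    t_start, x_start = kin.approach_start(cycle)
    d_at_start = distance_from_lateral(x_start, geo)
    if dd >= d_at_start:
        return t_start
    # Approach is decreasing x; distance <= dd iff |x - b| <= x_dd.
    x_dd = math.sqrt(max(0.0, dd * dd - geo.eye_screen_distance**2))
    x_target = geo.eye_opposite_x + x_dd
    if x_start < x_target:
        # starts inside the band yet farther than dd cannot happen; starting
        # below the band means the leg only ever moves away from it
        raise ValueError(f"dd={dd} not attainable on the approach leg of cycle {cycle}")
    t_hit = t_start + (x_start - x_target) / kin.speed
    if x_target < 0.0:
        raise ValueError(f"dd={dd} not reached before the approach leg ends")
    return t_hit


def glyph_extent(glyph: GlyphSpec, screen: ScreenSpec) -> float:
    """Outer extent of the glyph in mm (span in pixel pitches x pitch)."""
    return glyph.extent_pitches * screen.pixel_pitch


def angular_size(width: float, distance: float) -> float:
    """Full visual angle in degrees subtended by ``width`` at ``distance``."""
    if width <= 0 or distance <= 0:
        raise ValueError("width and distance must be positive")
    return math.degrees(2.0 * math.atan(width / (2.0 * distance)))


def angular_speed(t: float, kin: StimulusKinematics, geo: EyeGeometry) -> float:
    """Retinal angular speed of the glyph at time ``t`` in degrees/s.

    Zero during dwell phases and outside the motion window.
    """
    phase, x = phase_at(t, kin)
    if phase not in (Phase.APPROACH, Phase.RECEDE):
        return 0.0
    bc = geo.eye_screen_distance
    lateral = x - geo.eye_opposite_x
    return math.degrees(kin.speed * bc / (bc * bc + lateral * lateral))
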