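"""Virtual open-loop stimulus geometry and camera-display calibration.

All stimuli here are *virtual open loop*: their world positions are
continuously re-anchored to the live pose (centroid and heading) of a freely
swimming fish, so a rigid transform of the pose transforms stimulus
positions identically.  Angles follow the package's reporting convention
(counterclockwise-positive mathematical angles; a math angle ``h`` maps to
the image direction ``(cos h, -sin h)``).  Positive bearings are to the
fish's left; the prey-arc yaw angle uses the opposite sign (left = negative)
and is documented on :func:`prey_position`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "CalibrationParameters",
    "LoomingConfig",
    "OmrGratingState",
    "PreyArcConfig",
    "calibrate",
    "looming_angle",
    "omr_grating_state",
    "prey_position",
]


def _math_dir(angle: float) -> np.ndarray:
    return np.array([math.cos(angle), -math.sin(angle)])


# ---------------------------------------------------------------------------
# looming dot
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LoomingConfig:
    """Looming-dot parameters.

    ``l_over_v`` is the half-size-to-approach-speed ratio in seconds (0.09 s
    = 90 ms); the visual angle follows ``theta(t) = 2*atan(l_over_v /
    (t_c - t))`` and is clamped at ``max_angle`` once truncation is reached,
    ``expansion_duration`` seconds after expansion onset.  The dot sits at
    ``bearing`` degrees from the heading (positive = fish's left) at
    ``distance`` from the centroid.
    """

    l_over_v: float = 0.09
    static_duration: float = 10.0
    max_angle: float = 120.0
    expansion_duration: float = 3.0
    bearing: float = 90.0
    distance: float = 10.0

    def __post_init__(self) -> None:
        if self.l_over_v <= 0:
            raise ValueError("l_over_v must be positive")
        if not 0 < self.max_angle < 180:
            raise ValueError("max_angle must be in (0, 180) degrees")

    @property
    def collision_time(self) -> float:
        """Virtual time-to-collision t_c from trial start."""
        residual = self.l_over_v / math.tan(math.radians(self.max_angle) / 2.0)
        return self.static_duration + self.expansion_duration + residual

    @classmethod
    def left(cls, **kw) -> "LoomingConfig":
        return cls(bearing=90.0, **kw)

    @classmethod
    def right(cls, **kw) -> "LoomingConfig":
        return cls(bearing=-90.0, **kw)


def looming_angle(
    t: float,
    cfg: LoomingConfig,
    centroid: tuple[float, float] | None = None,
    heading: float | None = None,
) -> tuple[float, np.ndarray | None]:
    """Visual angle (deg) of the looming dot at time ``t``, plus its center.

    During the static period the angle is held at its expansion-onset value;
    afterwards it expands as ``2*atan(l_over_v / (t_c - t))`` until the
    truncation angle, where it clamps.  When the fish pose is given, the dot
    center is placed at the configured bearing and distance relative to the
    live pose, in the same units as the centroid.
    """
    t_c = cfg.collision_time
    t_eff = max(t, cfg.static_duration)
    residual = t_c - t_eff
    if residual <= 0:
        angle = cfg.max_angle
    else:
        angle = math.degrees(2.0 * math.atan(cfg.l_over_v / residual))
        angle = min(angle, cfg.max_angle)
    pos = None
    if centroid is not None and heading is not None:
        pos = np.asarray(centroid, float) + cfg.distance * _math_dir(
            heading + math.radians(cfg.bearing)
        )
    return angle, pos


# ---------------------------------------------------------------------------
# heading-locked optomotor grating
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OmrGratingState:
    orientation: float  # drift direction, math radians
    pivot: tuple[float, float]
    phase: float  # cycles, in [0, 1)


def omr_grating_state(
    centroid: tuple[float, float],
    heading: float,
    relative_direction_deg: float,
    t: float = 0.0,
    velocity: float = 1.0,
    spatial_period: float = 1.0,
) -> OmrGratingState:
    """Heading-locked drifting grating state.

    Drift direction is the heading plus the relative direction (+/-90 deg in
    the assay); the pivot is the fish centroid; the phase advances at
    ``velocity / spatial_period`` cycles per second (1 cm/s over a 1 cm
    period by default, i.e. 1 Hz temporal frequency).
    """
    orientation = heading + math.radians(relative_direction_deg)
    phase = (velocity / spatial_period * t) % 1.0
    return OmrGratingState(orientation, tuple(np.asarray(centroid, float)), phase)


# ---------------------------------------------------------------------------
# prey arc
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PreyArcConfig:
    """Virtual prey sweeping a +/-60 deg arc at 5 mm radius.

    In ``sweeping`` mode the arc angle is ``phi(t) = halfwidth * sin(w*t)``
    with ``w = peak_speed / halfwidth``, so the angular speed peaks at
    ``peak_speed`` (100 deg/s) directly ahead and falls to 0 at the arc
    ends.  ``fixed_lateral`` pins the dot at one lateral extreme.
    """

    arc_halfwidth: float = 60.0
    radius: float = 5.0
    peak_speed: float = 100.0
    mode: str = "sweeping"
    fixed_side: str = "left"
    dot_diameter: float = 1.0

    def __post_init__(self) -> None:
        if self.peak_speed <= 0 or self.radius <= 0:
            raise ValueError("peak_speed and radius must be positive")
        if self.mode not in ("sweeping", "fixed_lateral"):
            raise ValueError("mode must be 'sweeping' or 'fixed_lateral'")


def prey_position(
    t: float,
    centroid: tuple[float, float],
    heading: float,
    cfg: PreyArcConfig,
) -> tuple[np.ndarray, float]:
    """Dot position and prey yaw angle (deg) at time ``t``.

    The yaw angle is the dot's bearing from the heading with *left
    negative*: a dot pinned at the fish's left lateral extreme reads
    -60 deg.  The dot sits at ``cfg.radius`` from the centroid along that
    bearing.
    """
    if cfg.mode == "sweeping":
        w = cfg.peak_speed / cfg.arc_halfwidth
        yaw = -cfg.arc_halfwidth * math.sin(w * t)
    else:
        yaw = -cfg.arc_halfwidth if cfg.fixed_side == "left" else cfg.arc_halfwidth
    # left = positive mathematical bearing, so negate the yaw sign convention
    pos = np.asarray(centroid, float) + cfg.radius * _math_dir(
        heading + math.radians(-yaw)
    )
    return pos, yaw


# ---------------------------------------------------------------------------
# camera <-> display calibration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CalibrationParameters:
    """Affine map from camera space to display space (homogeneous 3x3)."""

    matrix: np.ndarray

    def map_point(self, p) -> np.ndarray:
        x, y = p
        v = self.matrix @ np.array([x, y, 1.0])
        return v[:2]

    def inverse(self) -> "CalibrationParameters":
        return CalibrationParameters(np.linalg.inv(self.matrix))


def _corners(rect: tuple[float, float, float, float]) -> np.ndarray:
    x, y, w, h = rect
    return np.array([[x, y], [x + w, y], [x + w, y + h], [x, y + h]], float)


def calibrate(
    camera_rect: tuple[float, float, float, float],
    display_rect: tuple[float, float, float, float],
) -> CalibrationParameters:
    """Affine map taking the camera rectangle's corners to the display's.

    Rectangles are (x, y, width, height); degenerate rectangles are
    rejected.  The least-squares solve over the four corner correspondences
    is exact for axis-aligned rectangles (round-trip error < 0.5 px).
    """
    for name, rect in (("camera", camera_rect), ("display", display_rect)):
        if rect[2] == 0 or rect[3] == 0:
            raise ValueError(f"{name} rectangle is degenerate")
    src = _corners(camera_rect)
    dst = _corners(display_rect)
    a = np.zeros((8, 6))
    b = np.zeros(8)
    a[0::2, 0:2] = src
    a[0::2, 2] = 1.0
    a[1::2, 3:5] = src
    a[1::2, 5] = 1.0
    b[0::2] = dst[:, 0]
    b[1::2] = dst[:, 1]
    coef, *_ = np.linalg.lstsq(a, b, rcond=None)
    m = np.array(
        [
            [coef[0], coef[1], coef[2]],
            [coef[3], coef[4], coef[5]],
            [0.0, 0.0, 1.0],
        ]
    )
    return CalibrationParameters(m)
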