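"""Tail curvature, online bout/tail-beat detection, heading and eye angles.

The curvature of a fitted tail is the array of bearings between successive
tail points expressed in a frame rotated so the centroid-to-tail-base
direction is zero; the heading used for that rotation carries the sign flip
``theta_h = -atan2(dy, dx)`` that converts y-down image geometry into
counterclockwise-positive reported angles.  An online detector turns the
scalar tail angle into bout instances, signed peak amplitudes and tail-beat
frequency, frame by frame, using only thresholds and a short ring buffer --
no spectral estimation.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass

import numpy as np

__all__ = [
    "BoutDetector",
    "BoutFeatures",
    "HeadingTracker",
    "TailKinematics",
    "calculate_eye_angles",
    "calculate_tail_curvature",
    "clean_heading_trace",
    "compute_bout_features",
    "detect_tail_beat",
    "segment_bouts",
    "tail_angle",
    "unwrap_curvature",
]


def _wrap(a: float) -> float:
    return (a + math.pi) % (2.0 * math.pi) - math.pi


# ---------------------------------------------------------------------------
# curvature
# ---------------------------------------------------------------------------


def calculate_tail_curvature(points: np.ndarray) -> np.ndarray:
    """Convert tail points into the curvature array Theta.

    The heading is taken from the centroid (first point) to the most rostral
    tail point (second point) with the reporting sign flip; all points are
    translated so the centroid sits at the origin and rotated by the heading,
    and the output angles are the bearings between successive points in the
    rotated frame, so the first angle is always exactly 0.  The result is
    unwrapped so successive angles never differ by more than pi.

    The output has one angle per tail segment: ``len(points) - 1`` values.
    """
    pts = np.asarray(points, float)
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 tail points")
    diffs = np.diff(pts, axis=0)
    if np.any((diffs == 0).all(axis=1)):
        raise ValueError("coincident consecutive tail points: bearing undefined")
    th = -math.atan2(pts[1, 1] - pts[0, 1], pts[1, 0] - pts[0, 0])
    c, s = math.cos(th), math.sin(th)
    tx = pts[:, 0] - pts[0, 0]
    ty = pts[:, 1] - pts[0, 1]
    xs = tx * c - ty * s
    ys = tx * s + ty * c
    theta = np.arctan2(np.diff(ys), np.diff(xs))
    return unwrap_curvature(theta)


def unwrap_curvature(theta: np.ndarray) -> np.ndarray:
    """Offset angles by multiples of 2*pi so successive differences stay <= pi.

    Applied iteratively along the array; idempotent.
    """
    theta = np.asarray(theta, float).copy()
    if theta.size == 0:
        raise ValueError("empty curvature array")
    for i in range(1, theta.size):
        while theta[i] - theta[i - 1] > math.pi:
            theta[i] -= 2.0 * math.pi
        while theta[i] - theta[i - 1] < -math.pi:
            theta[i] += 2.0 * math.pi
    return theta


def tail_angle(theta: np.ndarray) -> float:
    """Scalar tail angle: mean curvature of the last three tail segments."""
    theta = np.asarray(theta, float)
    if theta.size < 3:
        raise ValueError("need at least 3 curvature values")
    return float(theta[-3:].mean())


# ---------------------------------------------------------------------------
# online bout / tail-beat detection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TailKinematics:
    frequency: float
    amplitude: float
    bout_instance: bool


class BoutDetector:
    """Online threshold-based bout and tail-beat-frequency detector.

    A bout starts when the current tail angle departs from the running
    window extremum by more than ``bout_threshold`` (rad).  Within a bout the
    detector alternates between searching for maxima and minima; a peak is
    registered once the angle retreats from the running extremum by more than
    ``peak_threshold``, setting the signed peak amplitude.  After two peaks
    of the same direction, the frequency is ``frame_rate`` divided by the
    frame count of the full oscillation cycle between them (so a 20 Hz sine
    reads 20 Hz); set ``half_cycle_frequency=True`` to divide by the
    opposite-peak spacing instead.  When ``frame_window`` frames elapse
    without the bout threshold re-triggering, the bout ends and frequency and
    amplitude return to 0.  ``frame_window`` defaults to
    ``round(0.15 * frame_rate)``.
    """

    def __init__(
        self,
        bout_threshold: float,
        peak_threshold: float,
        frame_rate: float,
        frame_window: int | None = None,
        half_cycle_frequency: bool = False,
    ):
        if frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        self.bout_threshold = float(bout_threshold)
        self.peak_threshold = float(peak_threshold)
        self.frame_rate = float(frame_rate)
        self.frame_window = (
            int(round(0.15 * frame_rate)) if frame_window is None else int(frame_window)
        )
        self.half_cycle_frequency = half_cycle_frequency
        self._window: deque[float] = deque(maxlen=self.frame_window)
        self._frame = -1
        self._reset_bout()

    def _reset_bout(self) -> None:
        self.in_bout = False
        self.counter = 0
        self.frequency = 0.0
        self.amplitude = 0.0
        self._search_dir = 0
        self._ext_val = 0.0
        self._ext_frame = -1
        self._last_peak: dict[int, int] = {}

    def update(self, angle: float) -> TailKinematics:
        if not math.isfinite(angle):
            raise ValueError("non-finite tail angle")
        self._frame += 1
        if self._window:
            wmin = min(self._window)
            wmax = max(self._window)
            up = angle - wmin > self.bout_threshold
            down = wmax - angle > self.bout_threshold
        else:
            up = down = False

        if not self.in_bout:
            if up or down:
                self.in_bout = True
                self.counter = 0
                self._search_dir = 1 if up else -1
                self._ext_val = angle
                self._ext_frame = self._frame
                self._last_peak = {}
        else:
            self.counter += 1
            if up or down:
                self.counter = 0  # re-trigger keeps the bout alive
            if self._search_dir > 0:
                if angle > self._ext_val:
                    self._ext_val, self._ext_frame = angle, self._frame
                elif self._ext_val - angle > self.peak_threshold:
                    self._register_peak()
            else:
                if angle < self._ext_val:
                    self._ext_val, self._ext_frame = angle, self._frame
                elif angle - self._ext_val > self.peak_threshold:
                    self._register_peak()
            if self.counter > self.frame_window:
                self._reset_bout()
        self._window.append(angle)
        return TailKinematics(self.frequency, self.amplitude, self.in_bout)

    def _register_peak(self) -> None:
        direction = self._search_dir
        self.amplitude = self._ext_val
        key = 0 if self.half_cycle_frequency else direction
        prev = self._last_peak.get(key)
        if prev is not None and self._ext_frame > prev:
            self.frequency = self.frame_rate / (self._ext_frame - prev)
        self._last_peak[key] = self._ext_frame
        self._search_dir = -direction
        # the next extremum search starts fresh: +inf when hunting a minimum,
        # -inf when hunting a maximum
        self._ext_val = math.inf if direction > 0 else -math.inf
        self._ext_frame = self._frame


def detect_tail_beat(
    angles: np.ndarray,
    bout_threshold: float,
    peak_threshold: float,
    frame_rate: float,
    frame_window: int | None = None,
) -> dict[str, np.ndarray]:
    """Run :class:`BoutDetector` over a whole trace.

    Returns per-frame arrays ``bout`` (bool), ``frequency`` (Hz) and
    ``amplitude`` (rad, signed).
    """
    det = BoutDetector(bout_threshold, peak_threshold, frame_rate, frame_window)
    n = len(angles)
    bout = np.zeros(n, bool)
    freq = np.zeros(n)
    amp = np.zeros(n)
    for i, a in enumerate(np.asarray(angles, float)):
        k = det.update(a)
        bout[i], freq[i], amp[i] = k.bout_instance, k.frequency, k.amplitude
    return {"bout": bout, "frequency": freq, "amplitude": amp}


# ---------------------------------------------------------------------------
# bout segmentation and per-bout features
# ---------------------------------------------------------------------------


def segment_bouts(
    bout_flags: np.ndarray, fps: float, pad_s: float = 0.015
) -> list[tuple[int, int]]:
    """Half-open ``[start, stop)`` bout intervals with padding on both sides.

    Maximal runs of true flags are each extended by ``round(pad_s * fps)``
    frames before and after, clipped to the record; padded intervals that
    touch or overlap are merged.
    """
    if fps <= 0:
        raise ValueError("fps must be positive")
    flags = np.asarray(bout_flags, bool)
    n = flags.size
    pad = int(round(pad_s * fps))
    edges = np.flatnonzero(np.diff(np.concatenate(([0], flags.view(np.int8), [0]))))
    raw = list(zip(edges[::2], edges[1::2]))
    merged: list[tuple[int, int]] = []
    for s, e in raw:
        s = max(0, int(s) - pad)
        e = min(n, int(e) + pad)
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


@dataclass(frozen=True)
class BoutFeatures:
    """Per-bout kinematic summary.

    ``integral`` and ``max_amplitude`` keep their signs; absolute values are
    taken only at clustering time.
    """

    mean_tbf: float
    integral: float
    sd: float
    max_amplitude: float
    start_frame: int
    end_frame: int


def compute_bout_features(
    tail_angles: np.ndarray,
    tbf: np.ndarray,
    interval: tuple[int, int],
    fps: float,
) -> BoutFeatures:
    """Summarize one padded bout interval (half-open frame range)."""
    start, stop = interval
    angles = np.asarray(tail_angles, float)
    tbf = np.asarray(tbf, float)
    if not (0 <= start < stop <= angles.size):
        raise ValueError("interval outside record")
    seg = angles[start:stop]
    f = tbf[start:stop]
    nz = f[f > 0]
    return BoutFeatures(
        mean_tbf=float(nz.mean()) if nz.size else 0.0,
        integral=float(seg.sum() / fps),
        sd=float(seg.std()),
        max_amplitude=float(seg[np.argmax(np.abs(seg))]) if seg.size else 0.0,
        start_frame=int(start),
        end_frame=int(stop),
    )


# ---------------------------------------------------------------------------
# eye angles and heading
# ---------------------------------------------------------------------------


def calculate_eye_angles(eyes, theta_h: float) -> tuple[float, float]:
    """Per-eye angle relative to the heading, in (-pi/2, pi/2].

    For each eye a point is constructed at distance ``l_M`` (the major-axis
    length) and angle ``theta_M`` (the major-axis orientation, defined only
    modulo pi) from the origin, rotated by the heading ``theta_h``, and the
    angle of the rotated point is taken.  Because the axis orientation is
    ambiguous by pi, the result is offset by pi when it initially points
    opposite the heading.
    """
    out = []
    c, s = math.cos(theta_h), math.sin(theta_h)
    for eye in eyes:
        l_m = eye.major_axis
        if l_m <= 0:
            raise ValueError("major axis length must be positive")
        x = l_m * math.cos(eye.orientation)
        y = l_m * math.sin(eye.orientation)
        xs = x * c - y * s
        ys = x * s + y * c
        ang = math.atan2(ys, xs)
        while ang > math.pi / 2.0:
            ang -= math.pi
        while ang <= -math.pi / 2.0:
            ang += math.pi
        out.append(ang)
    return tuple(out)


class HeadingTracker:
    """Cumulative (unbounded) heading angle across frames.

    The instantaneous heading is the reported-convention angle from the
    centroid to the midpoint of the two eye centroids, or -- in the tail
    variant -- from the most rostral tail point toward the centroid.
    Cross-frame changes are unwrapped so the cumulative trace never jumps by
    more than pi per frame; optionally the first sample is zeroed.
    """

    def __init__(self, initialize_to_zero: bool = False):
        self.initialize_to_zero = initialize_to_zero
        self.cumulative: float | None = None
        self._last_raw: float | None = None

    def update(self, *, eyes=None, centroid=None, tail_points=None) -> float:
        if eyes is not None and centroid is not None:
            (lx, ly), (rx, ry) = eyes[0].centroid, eyes[1].centroid
            mx, my = (lx + rx) / 2.0, (ly + ry) / 2.0
            cx, cy = centroid
            raw = -math.atan2(my - cy, mx - cx)
        elif tail_points is not None:
            pts = np.asarray(tail_points, float)
            raw = -math.atan2(pts[0, 1] - pts[1, 1], pts[0, 0] - pts[1, 0])
        else:
            raise ValueError("need eyes+centroid or tail_points")
        if self.cumulative is None:
            self.cumulative = 0.0 if self.initialize_to_zero else raw
        else:
            self.cumulative += _wrap(raw - self._last_raw)
        self._last_raw = raw
        return self.cumulative


def clean_heading_trace(series: np.ndarray, fps: float) -> np.ndarray:
    """Remove implausible heading jumps (> 180 deg per 10 ms) from a trace.

    Spans of ``round(0.01 * fps)`` frames whose endpoints differ by more than
    pi are excised (set to NaN) and all subsequent values are shifted so the
    first post-gap value matches the value before the gap.  Consecutive
    artifacts compose.  Input and output are radians.
    """
    if fps <= 0:
        raise ValueError("fps must be positive")
    s = np.asarray(series, float).copy()
    n = s.size
    w = max(1, int(round(0.01 * fps)))
    removed = np.zeros(n, bool)
    i = w
    while i < n:
        if abs(s[i] - s[i - w]) > math.pi:
            delta = s[i] - s[i - w]
            removed[i - w + 1 : i + 1] = True
            # clamp the gap so later spans do not re-trigger on it
            s[i - w + 1 : i + 1] = s[i - w]
            if i + 1 < n:
                s[i + 1 :] -= delta
            i += 1
        else:
            i += 1
    out = s
    out[removed] = np.nan
    return out
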