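"""Iterative point-to-point contrast-based tail-point fitting.

Tail points are fitted one at a time on precomputed rasterized circles.  The
first (most rostral) point is searched on a circle of radius
``dist_tail_base`` around the centroid -- over the full circle when no
heading is supplied, or taken directly at the angle opposite the heading when
one is.  Each subsequent point is searched on an arc of the
``dist_tail_points`` circle centered on the direction of the previous tail
segment, which also guarantees the fitted polyline never doubles back by
more than half the arc range.  Three point scorers are available: the
extremal pixel (fast but jittery), the contrast-weighted median along the
arc, and the arc point nearest the contrast center of mass (both smoother
frame to frame).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

__all__ = ["TailFitConfig", "calculate_tail_points", "precompute_circle_points"]


@dataclass(frozen=True)
class TailFitConfig:
    """Configuration mirroring the tracker's tail-fitting properties.

    ``heading_direction`` is a mathematical angle in [0, 2*pi); any negative
    value is the "unset" sentinel selecting a full-circle search for the
    first tail point.  ``range_tail_point_angles`` is the total angular
    length of the search arc.
    """

    dist_tail_base: float = 12.0
    dist_tail_points: float = 6.0
    range_tail_point_angles: float = 2.0 * math.pi / 3.0
    num_tail_segments: int = 7
    method: str = "weighted_median"
    pixel_polarity: str = "darkest"
    heading_direction: float = -1.0
    offset_x: float = 0.0
    offset_y: float = 0.0

    def __post_init__(self) -> None:
        if min(self.dist_tail_base, self.dist_tail_points) < 1:
            raise ValueError("circle radii must be >= 1 px")
        if not (0.0 < self.range_tail_point_angles <= 2.0 * math.pi):
            raise ValueError("range_tail_point_angles must be in (0, 2*pi]")
        if self.num_tail_segments < 1:
            raise ValueError("num_tail_segments must be >= 1")
        if self.method not in ("pixel_search", "weighted_median", "center_of_mass"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.pixel_polarity not in ("darkest", "lightest"):
            raise ValueError("pixel_polarity must be 'darkest' or 'lightest'")


@lru_cache(maxsize=64)
def precompute_circle_points(radius: int) -> tuple[np.ndarray, np.ndarray]:
    """Rasterized circle of the given radius, sorted by polar angle.

    For each finely sampled ideal angle, the integer point among the four
    surrounding lattice corners with the smallest radial error is kept; this
    bounds every point's distance from the ideal circle by 0.5 px.  Returns
    ``(points, angles)`` where ``points`` is an ``(n, 2)`` integer array of
    (x, y) offsets (image convention, y down) and ``angles`` the cached
    ``atan2(y, x)`` of each point, strictly increasing.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    n = max(32, int(math.ceil(2.0 * math.pi * radius * 4)))
    thetas = np.linspace(-math.pi, math.pi, n, endpoint=False)
    ix, iy = radius * np.cos(thetas), radius * np.sin(thetas)
    best = {}
    for x, y in zip(ix, iy):
        cands = [
            (math.floor(x) + dx, math.floor(y) + dy)
            for dx in (0, 1)
            for dy in (0, 1)
        ]
        px, py = min(cands, key=lambda p: abs(math.hypot(*p) - radius))
        best[(px, py)] = True
    pts = np.array(sorted(best, key=lambda p: math.atan2(p[1], p[0])), dtype=int)
    angles = np.arctan2(pts[:, 1], pts[:, 0])
    return pts, angles


def _circular_diff(a: np.ndarray, b: float) -> np.ndarray:
    return (a - b + math.pi) % (2.0 * math.pi) - math.pi


def _score(
    intensities: np.ndarray, positions: np.ndarray, method: str, polarity: str
) -> int:
    """Index of the selected arc point.  Ties break to the first point in
    arc traversal order."""
    vals = intensities.astype(float)
    if method == "pixel_search":
        return int(np.argmin(vals) if polarity == "darkest" else np.argmax(vals))
    # contrast weight: difference from the opposing extremum, so the most
    # fish-like pixels weigh the most
    weights = vals.max() - vals if polarity == "darkest" else vals - vals.min()
    total = weights.sum()
    if total <= 0.0:  # uniform arc: degenerate, pick the arc start
        return 0
    if method == "weighted_median":
        return int(np.searchsorted(np.cumsum(weights), total / 2.0))
    com = (weights[:, None] * positions).sum(axis=0) / total
    d2 = ((positions - com) ** 2).sum(axis=1)
    return int(np.argmin(d2))


def calculate_tail_points(
    frame: np.ndarray, centroid, cfg: TailFitConfig
) -> np.ndarray | None:
    """Fit ``num_tail_segments + 2`` points from the centroid to the tail tip.

    ``centroid`` is an (x, y) pair or a :class:`~zebtrack.blobs.Centroid`;
    ``None`` propagates a no-detection result.  The returned array has shape
    ``(num_tail_segments + 2, 2)`` ordered along the rostral-caudal axis,
    starting at the centroid.  Search arcs that partly exit the frame are
    clamped to the in-bounds points with a warning.
    """
    if centroid is None:
        return None
    if hasattr(centroid, "x"):
        cx, cy = float(centroid.x), float(centroid.y)
    else:
        cx, cy = float(centroid[0]), float(centroid[1])
    frame = np.asarray(frame)
    h, w = frame.shape

    def in_bounds(pos: np.ndarray) -> np.ndarray:
        return (
            (pos[:, 0] >= 0) & (pos[:, 0] < w) & (pos[:, 1] >= 0) & (pos[:, 1] < h)
        )

    base_pts, base_angles = precompute_circle_points(int(round(cfg.dist_tail_base)))
    step_pts, step_angles = precompute_circle_points(int(round(cfg.dist_tail_points)))

    points = [np.array([cx, cy])]
    if cfg.heading_direction < 0:
        cand = points[0] + base_pts
        ok = in_bounds(cand)
        if not ok.all():
            warnings.warn("tail-base search circle clamped to frame bounds")
        cand = cand[ok]
        vals = frame[cand[:, 1].astype(int), cand[:, 0].astype(int)]
        idx = _score(vals, cand.astype(float), "pixel_search", cfg.pixel_polarity)
        points.append(cand[idx].astype(float))
    else:
        # point at the circle angle opposite the provided heading; the
        # heading is a mathematical angle, circle angles are image-space
        target = math.atan2(math.sin(cfg.heading_direction), -math.cos(cfg.heading_direction))
        idx = int(np.argmin(np.abs(_circular_diff(base_angles, target))))
        points.append(points[0] + base_pts[idx])

    for _ in range(cfg.num_tail_segments):
        prev2, prev1 = points[-2], points[-1]
        seg = prev1 - prev2
        target = math.atan2(seg[1], seg[0])
        offsets = _circular_diff(step_angles, target)
        sel = np.abs(offsets) <= cfg.range_tail_point_angles / 2.0
        order = np.argsort(offsets[sel], kind="stable")
        arc = step_pts[sel][order]
        cand = prev1 + arc
        ok = in_bounds(cand)
        if not ok.all():
            warnings.warn("tail search arc clamped to frame bounds")
            cand = cand[ok]
        if cand.shape[0] == 0:
            raise ValueError("tail search arc left the frame entirely")
        vals = frame[cand[:, 1].astype(int), cand[:, 0].astype(int)]
        idx = _score(vals, cand.astype(float), cfg.method, cfg.pixel_polarity)
        points.append(cand[idx].astype(float))

    out = np.asarray(points, float)
    out[:, 0] += cfg.offset_x
    out[:, 1] += cfg.offset_y
    return out
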