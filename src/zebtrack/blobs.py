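"""Centroid extraction and eye-region extraction from thresholded frames.

Centroids come either from the raw image moments of the whole thresholded
mask or from the largest connected region within an area range.  Eye regions
are connected components filtered by area, by distance from the fish
centroid, and by bearing relative to the heading direction; the two
survivors are ordered (left, right), where "left" is the fish's own left --
the region with positive signed bearing from the heading in the
counterclockwise-positive reporting convention (images are y-down).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage.measure import label, regionprops

__all__ = [
    "Centroid",
    "EyeDetectionError",
    "EyeRegion",
    "calculate_centroid",
    "find_eye_contours",
]


@dataclass(frozen=True)
class Centroid:
    x: float
    y: float
    method: str
    region_area: float | None = None


@dataclass(frozen=True)
class EyeRegion:
    """One eye as a connected component with an ellipse-like summary.

    ``orientation`` (theta_M) is the major-axis direction as a mathematical
    angle in [0, pi).
    """

    centroid: tuple[float, float]
    area: float
    major_axis: float
    orientation: float
    side: str


class EyeDetectionError(RuntimeError):
    """Raised when the survivor count after filtering is not exactly two."""

    def __init__(self, count: int):
        super().__init__(f"eye detection found {count} candidate regions, expected 2")
        self.count = count


def _threshold(img: np.ndarray, value: float, kind: str) -> np.ndarray:
    img = np.asarray(img)
    if kind == "binary":
        return img > value
    if kind == "inverted":
        return img <= value
    raise ValueError("threshold_type must be 'binary' or 'inverted'")


def calculate_centroid(
    img: np.ndarray,
    threshold_value: float,
    threshold_type: str = "binary",
    method: str = "largest_binary_region",
    min_area: float = 0.0,
    max_area: float = math.inf,
    prev: tuple[float, float] | None = None,
) -> Centroid | None:
    """Locate the animal's centroid in an 8-bit frame.

    ``raw_image_moments`` takes the center of mass of the whole thresholded
    mask.  ``largest_binary_region`` labels connected components, discards
    those with area outside ``[min_area, max_area]`` and returns the centroid
    of the largest survivor.  Ties on area break toward the region nearest
    ``prev`` (the previous frame's centroid) when given, else to the
    topmost-leftmost region.

    Returns ``None`` when nothing is detected (empty mask, or no region in
    the area range) -- an explicit no-detection result, never ``(0, 0)``.
    """
    mask = _threshold(img, threshold_value, threshold_type)
    if method == "raw_image_moments":
        ys, xs = np.nonzero(mask)
        if xs.size == 0:
            return None
        return Centroid(float(xs.mean()), float(ys.mean()), method)
    if method != "largest_binary_region":
        raise ValueError(
            "method must be 'raw_image_moments' or 'largest_binary_region'"
        )
    regions = [
        r
        for r in regionprops(label(mask, connectivity=2))
        if min_area <= r.area <= max_area
    ]
    if not regions:
        return None
    best_area = max(r.area for r in regions)
    ties = [r for r in regions if r.area == best_area]
    if len(ties) > 1 and prev is not None:
        px, py = prev
        ties.sort(
            key=lambda r: (r.centroid[1] - px) ** 2 + (r.centroid[0] - py) ** 2
        )
    else:
        ties.sort(key=lambda r: (r.centroid[0], r.centroid[1]))
    chosen = ties[0]
    cy, cx = chosen.centroid
    return Centroid(float(cx), float(cy), method, float(chosen.area))


def _math_angle(dx: float, dy: float) -> float:
    # image-space vector -> counterclockwise-positive mathematical angle
    return math.atan2(-dy, dx)


def _wrap(a: float) -> float:
    return (a + math.pi) % (2.0 * math.pi) - math.pi


def _major_axis_orientation(coords: np.ndarray) -> float:
    """Major-axis direction of a pixel region, math convention, in [0, pi)."""
    ys = coords[:, 0].astype(float)
    xs = coords[:, 1].astype(float)
    x = xs - xs.mean()
    y = -(ys - ys.mean())  # flip to y-up
    mu20 = np.mean(x * x)
    mu02 = np.mean(y * y)
    mu11 = np.mean(x * y)
    return 0.5 * math.atan2(2.0 * mu11, mu20 - mu02) % math.pi


def find_eye_contours(
    mask: np.ndarray,
    tail_points: np.ndarray,
    min_area: float,
    max_area: float,
    min_distance: float,
    max_distance: float,
    angle_range: float,
    fit_ellipses: bool = True,
) -> tuple[EyeRegion, EyeRegion]:
    """Extract the left and right eye from a binary image.

    ``tail_points`` supplies the fish centroid (first point) and heading
    (direction from the first tail point toward the centroid).  Candidate
    regions are kept when their area lies in ``[min_area, max_area]``, their
    centroid distance from the fish centroid lies in
    ``[min_distance, max_distance]`` and their bearing is within
    ``+/- angle_range / 2`` of the heading.  Exactly two survivors are
    expected; they are returned ordered (left, right) by signed bearing.

    When ``fit_ellipses`` is true the major-axis length and orientation come
    from the moment-equivalent ellipse of the region; otherwise the raw
    bounding-box diagonal stands in for the axis length.
    """
    pts = np.asarray(tail_points, float)
    if pts.shape[0] < 2:
        raise ValueError("tail_points must hold at least centroid and tail base")
    cx, cy = pts[0]
    heading = _math_angle(pts[0, 0] - pts[1, 0], pts[0, 1] - pts[1, 1])

    candidates = []
    for r in regionprops(label(np.asarray(mask) > 0, connectivity=2)):
        if not (min_area <= r.area <= max_area):
            continue
        ry, rx = r.centroid
        d = math.hypot(rx - cx, ry - cy)
        if not (min_distance <= d <= max_distance):
            continue
        bearing = _wrap(_math_angle(rx - cx, ry - cy) - heading)
        if abs(bearing) > angle_range / 2.0:
            continue
        candidates.append((bearing, r))
    if len(candidates) != 2:
        raise EyeDetectionError(len(candidates))
    # candidates were pre-filtered by |bearing|; final order is by signed
    # bearing, positive (left) first
    candidates.sort(key=lambda br: -br[0])
    out = []
    for side, (bearing, r) in zip(("left", "right"), candidates):
        ry, rx = r.centroid
        if fit_ellipses:
            major = float(r.axis_major_length)
        else:
            h = r.bbox[2] - r.bbox[0]
            w = r.bbox[3] - r.bbox[1]
            major = float(math.hypot(h, w))
        out.append(
            EyeRegion(
                centroid=(float(rx), float(ry)),
                area=float(r.area),
                major_axis=major,
                orientation=_major_axis_orientation(r.coords),
                side=side,
            )
        )
    return out[0], out[1]
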