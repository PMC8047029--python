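"""Ground-truthed synthetic fixtures: rendered fish, swim traces, prey paths.

Every generator takes an explicit seed; there is no global random state.
Rendered fish are deliberately simple -- a Gaussian-profile body blob, two
eye ellipses rostral to the centroid, and a smooth anti-aliased tail stroke --
which is exactly the appearance the contrast-based tracking stack assumes
(a compact dark (or light) subject on an opposing background).  Pigment
patterns, refraction and projector light are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import distance_transform_edt

__all__ = [
    "EyeEllipse",
    "FishPose",
    "RenderGroundTruth",
    "SwimBout",
    "SwimTraceSpec",
    "default_eyes",
    "generate_bout_feature_clusters",
    "generate_prey_paths",
    "generate_swim_trace",
    "render_fish_frame",
    "tail_polyline",
]


@dataclass(frozen=True)
class EyeEllipse:
    """One eye modelled as a filled ellipse.

    ``orientation`` is the major-axis direction as a mathematical angle
    (counterclockwise-positive, y-up), taken modulo pi.
    """

    center: tuple[float, float]
    major_axis: float
    minor_axis: float
    orientation: float


@dataclass(frozen=True)
class FishPose:
    """Geometric description of a rendered fish.

    ``heading`` is a mathematical angle (counterclockwise-positive, 0 = +x);
    the tail extends in the opposite direction.  ``segment_angles`` are the
    successive inter-segment bend angles of the tail, so an all-zero tuple is
    a straight tail.  Intensities are 8-bit; they must differ by at least 20
    so that contrast-based detection is well-posed.
    """

    centroid: tuple[float, float]
    heading: float
    segment_angles: tuple[float, ...]
    segment_length: float = 7.0
    eyes: tuple[EyeEllipse, EyeEllipse] | None = None
    body_intensity: int = 30
    background_intensity: int = 200
    tail_contrast: float = 0.75
    body_radius: float = 3.0
    stroke_sigma: float = 1.3

    def __post_init__(self) -> None:
        if len(self.segment_angles) < 1:
            raise ValueError("pose needs at least one tail segment")
        if abs(self.body_intensity - self.background_intensity) < 20:
            raise ValueError(
                "body and background intensities must differ by >= 20"
            )
        if self.segment_length <= 0:
            raise ValueError("segment_length must be positive")


@dataclass(frozen=True)
class RenderGroundTruth:
    """Exact geometry behind a rendered frame."""

    polyline: np.ndarray  # (n_segments + 1, 2): centroid first, then vertices
    centroid: tuple[float, float]
    heading: float
    eyes: tuple[EyeEllipse, EyeEllipse] | None


def _math_dir(angle: float) -> np.ndarray:
    # mathematical angle -> image-space unit vector (y down)
    return np.array([np.cos(angle), -np.sin(angle)])


def default_eyes(
    centroid: tuple[float, float],
    heading: float,
    distance: float = 7.0,
    separation: float = 7.0,
    major_axis: float = 4.0,
    minor_axis: float = 2.2,
) -> tuple[EyeEllipse, EyeEllipse]:
    """Place two heading-aligned eye ellipses rostral to the centroid.

    The left eye (fish's own left, positive bearing in the reporting
    convention) comes first.
    """
    c = np.asarray(centroid, float)
    fwd = _math_dir(heading)
    left = _math_dir(heading + np.pi / 2.0)
    orient = heading % np.pi
    mk = lambda side: EyeEllipse(  # noqa: E731
        center=tuple(c + distance * fwd + side * (separation / 2.0) * left),
        major_axis=major_axis,
        minor_axis=minor_axis,
        orientation=orient,
    )
    return (mk(+1.0), mk(-1.0))


def tail_polyline(pose: FishPose) -> np.ndarray:
    """Ground-truth tail vertices, from the centroid to the tail tip.

    The first vertex is the centroid; each subsequent vertex extends one
    segment of ``segment_length`` in the direction opposite the heading,
    bent by the cumulative segment angles.
    """
    directions = pose.heading + np.pi + np.cumsum(pose.segment_angles)
    steps = pose.segment_length * np.stack(
        [np.cos(directions), -np.sin(directions)], axis=1
    )
    pts = np.vstack([np.zeros(2), np.cumsum(steps, axis=0)])
    return pts + np.asarray(pose.centroid, float)


def _splat_distance(shape: tuple[int, int], samples: np.ndarray) -> np.ndarray:
    """Per-pixel distance to a densely sampled curve."""
    occ = np.ones(shape, bool)
    rows = np.clip(np.round(samples[:, 1]).astype(int), 0, shape[0] - 1)
    cols = np.clip(np.round(samples[:, 0]).astype(int), 0, shape[1] - 1)
    occ[rows, cols] = False
    return distance_transform_edt(occ)


def render_fish_frame(
    pose: FishPose, size: tuple[int, int]
) -> tuple[np.ndarray, RenderGroundTruth]:
    """Render an 8-bit grayscale fish frame plus its exact ground truth.

    ``size`` is (height, width).  The tail is an anti-aliased stroke with a
    Gaussian cross-section through the ground-truth polyline; the body is a
    brighter-contrast Gaussian blob at the centroid and the eyes, when
    present, are filled ellipses.  Rendering is deterministic.

    Raises
    ------
    ValueError
        If the tail exits the frame; the message names the first
        out-of-bounds segment.
    """
    h, w = size
    poly = tail_polyline(pose)
    margin = 3.0 * pose.stroke_sigma
    for i, (x, y) in enumerate(poly):
        if not (margin <= x < w - margin and margin <= y < h - margin):
            raise ValueError(
                f"tail segment {i} at ({x:.1f}, {y:.1f}) exits the "
                f"{h}x{w} frame"
            )

    # dense resampling of the polyline for the stroke distance field
    seglens = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    samples = [poly[:1]]
    for p0, p1, L in zip(poly[:-1], poly[1:], seglens):
        n = max(2, int(np.ceil(L / 0.25)))
        t = np.linspace(0.0, 1.0, n)[1:, None]
        samples.append(p0[None, :] * (1 - t) + p1[None, :] * t)
    dist = _splat_distance((h, w), np.vstack(samples))

    contrast = float(pose.background_intensity - pose.body_intensity)
    depth = np.zeros((h, w), float)  # signed contrast to apply
    tail = (
        pose.tail_contrast
        * abs(contrast)
        * np.exp(-0.5 * (dist / pose.stroke_sigma) ** 2)
    )
    tail[dist > 4.0 * pose.stroke_sigma] = 0.0
    depth = np.maximum(depth, tail)

    yy, xx = np.mgrid[0:h, 0:w]
    cx, cy = pose.centroid
    r2 = (xx - cx) ** 2 + (yy - cy) ** 2
    body = abs(contrast) * np.exp(-0.5 * r2 / pose.body_radius**2)
    body[r2 <= pose.body_radius**2] = abs(contrast)
    depth = np.maximum(depth, body)

    if pose.eyes is not None:
        for eye in pose.eyes:
            ex, ey = eye.center
            # rotate pixel offsets into the eye frame (math angle, y down)
            ca, sa = np.cos(eye.orientation), np.sin(eye.orientation)
            u = (xx - ex) * ca - (yy - ey) * sa
            v = (xx - ex) * sa + (yy - ey) * ca
            inside = (u / (eye.major_axis / 2.0)) ** 2 + (
                v / (eye.minor_axis / 2.0)
            ) ** 2 <= 1.0
            depth[inside] = abs(contrast)

    if contrast >= 0:  # dark fish on light background
        img = pose.background_intensity - depth
    else:
        img = pose.background_intensity + depth
    frame = np.clip(np.round(img), 0, 255).astype(np.uint8)
    truth = RenderGroundTruth(
        polyline=poly,
        centroid=tuple(np.asarray(pose.centroid, float)),
        heading=pose.heading,
        eyes=pose.eyes,
    )
    return frame, truth


# ---------------------------------------------------------------------------
# swim traces
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SwimBout:
    """One scripted bout: ``amplitude*sin(2*pi*f*(t-onset)) + bias``."""

    onset: float
    duration: float
    beat_frequency: float
    amplitude: float
    bias: float = 0.0


@dataclass(frozen=True)
class SwimTraceSpec:
    fps: float
    duration: float
    bouts: tuple[SwimBout, ...] = ()
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        ordered = sorted(self.bouts, key=lambda b: b.onset)
        for a, b in zip(ordered[:-1], ordered[1:]):
            if a.onset + a.duration > b.onset:
                raise ValueError("bouts must not overlap")
        for b in self.bouts:
            if b.beat_frequency >= self.fps / 2.0:
                raise ValueError(
                    f"beat frequency {b.beat_frequency} Hz aliases at "
                    f"{self.fps} fps (Nyquist {self.fps / 2.0} Hz)"
                )


def generate_swim_trace(spec: SwimTraceSpec) -> dict[str, np.ndarray]:
    """Per-frame tail angle with exact per-frame ground truth.

    Returns a dict with keys ``angle`` (rad), ``bout`` (bool flags),
    ``frequency`` (instantaneous beat frequency, Hz, zero outside bouts)
    and ``peak_frames`` (float frame indices of the within-bout sinusoid
    extrema).
    """
    n = int(round(spec.fps * spec.duration))
    t = np.arange(n) / spec.fps
    angle = np.zeros(n)
    bout = np.zeros(n, bool)
    freq = np.zeros(n)
    peak_frames: list[float] = []
    for b in spec.bouts:
        mask = (t >= b.onset) & (t < b.onset + b.duration)
        angle[mask] = (
            b.amplitude * np.sin(2.0 * np.pi * b.beat_frequency * (t[mask] - b.onset))
            + b.bias
        )
        bout |= mask
        freq[mask] = b.beat_frequency
        # one ground-truth peak per full cycle (the positive extrema), so
        # peak-to-peak spacing equals the beat period fps/f in frames
        period = 1.0 / b.beat_frequency
        k = 0
        while True:
            tp = b.onset + (0.25 + k) * period
            if tp >= b.onset + b.duration:
                break
            peak_frames.append(tp * spec.fps)
            k += 1
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        angle = angle + rng.normal(0.0, spec.noise_sd, n)
    return {
        "angle": angle,
        "bout": bout,
        "frequency": freq,
        "peak_frames": np.array(peak_frames),
    }


# ---------------------------------------------------------------------------
# prey trajectories
# ---------------------------------------------------------------------------


def generate_prey_paths(
    n: int,
    arena: tuple[float, float],
    seed: int,
    duration: float = 10.0,
    fps: float = 60.0,
    speed_range: tuple[float, float] = (2.0, 10.0),
    run_distance_range: tuple[float, float] = (2.0, 10.0),
    pause_range: tuple[float, float] = (0.1, 0.6),
    angular_velocity_range: tuple[float, float] = (1.0, 6.0),
) -> np.ndarray:
    """Paramecia-like prey trajectories: runs, pauses, reorientations.

    Each prey alternates a straight run of randomized speed and distance, a
    brief pause, and a reorientation with randomized angular velocity and
    target orientation.  Paths reflect off the arena walls.  Returns an array
    of shape ``(n, frames, 2)`` in the same units as ``arena`` (width,
    height).

    Setting the angular-velocity and pause ranges to zero yields a
    straight-line path.
    """
    if n < 1:
        raise ValueError("need at least one prey")
    w, h = arena
    frames = int(round(duration * fps))
    dt = 1.0 / fps
    rng = np.random.default_rng(seed)
    out = np.zeros((n, frames, 2))
    for i in range(n):
        pos = np.array([rng.uniform(0.1 * w, 0.9 * w), rng.uniform(0.1 * h, 0.9 * h)])
        theta = rng.uniform(0.0, 2.0 * np.pi)
        mode = "run"
        speed = rng.uniform(*speed_range)
        remaining = rng.uniform(*run_distance_range)
        turn_rate = 0.0
        for f in range(frames):
            out[i, f] = pos
            if mode == "run":
                step = speed * dt
                pos = pos + step * np.array([np.cos(theta), np.sin(theta)])
                remaining -= step
                if remaining <= 0.0:
                    mode = "pause"
                    remaining = rng.uniform(*pause_range)
            elif mode == "pause":
                remaining -= dt
                if remaining <= 0.0:
                    mode = "turn"
                    turn_rate = rng.uniform(*angular_velocity_range) * rng.choice(
                        [-1.0, 1.0]
                    )
                    remaining = rng.uniform(0.0, np.pi) / max(abs(turn_rate), 1e-9)
            else:  # turn
                theta += turn_rate * dt
                remaining -= dt
                if remaining <= 0.0:
                    mode = "run"
                    speed = rng.uniform(*speed_range)
                    remaining = rng.uniform(*run_distance_range)
            # reflect at walls
            for ax, lim in ((0, w), (1, h)):
                if pos[ax] < 0.0:
                    pos[ax] = -pos[ax]
                    theta = np.pi - theta if ax == 0 else -theta
                elif pos[ax] > lim:
                    pos[ax] = 2.0 * lim - pos[ax]
                    theta = np.pi - theta if ax == 0 else -theta
    return out


# ---------------------------------------------------------------------------
# labelled bout-feature mixtures
# ---------------------------------------------------------------------------


def generate_bout_feature_clusters(
    n_per_class: int,
    class_params: list[tuple[np.ndarray, np.ndarray]],
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian draws per class in the 4-D bout-feature space.

    ``class_params`` is a list of (mean, sd) pairs in
    (mean TBF, |integral|, SD, |max amplitude|) space.  Returns ``(X, y)``
    with ``X`` of shape ``(n_classes * n_per_class, 4)`` and integer labels.
    """
    if len(class_params) < 2:
        raise ValueError("need at least two classes")
    rng = np.random.default_rng(seed)
    xs, ys = [], []
    for label, (mean, sd) in enumerate(class_params):
        mean = np.asarray(mean, float)
        sd = np.asarray(sd, float)
        if mean.shape != (4,) or sd.shape != (4,):
            raise ValueError("class means and SDs must be 4-vectors")
        if np.any(sd <= 0):
            raise ValueError("class SDs must be positive")
        xs.append(rng.normal(mean, sd, size=(n_per_class, 4)))
        ys.append(np.full(n_per_class, label))
    return np.vstack(xs), np.concatenate(ys)
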