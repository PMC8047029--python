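"""Pipeline orchestration and file formats.

Videos are either AVI/MP4 containers (through imageio, when a suitable
plugin is available) or directories of numbered PNG frames; color input is
converted to grayscale by luminance.  The offline tracking pipeline runs the
stages in acquisition order -- background subtraction, centroid calculation,
tail-point fitting, tail-angle calculation, online bout detection -- per
frame, and writes per-frame CSV records.  CSVs are comma-separated UTF-8
with a header row; angles are radians, frame indices 0-based, coordinates
pixel-space with the origin top-left.  Per-frame failures are logged and
leave null fields rather than aborting the run.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
import yaml

from .background import BackgroundModel
from .blobs import calculate_centroid
from .kinematics import BoutDetector, HeadingTracker, calculate_tail_curvature, tail_angle
from .multi import track_identities
from .tailfit import TailFitConfig, calculate_tail_points

__all__ = ["PipelineConfig", "read_video", "track_video"]

log = logging.getLogger("zebtrack")

_LUMA = np.array([0.299, 0.587, 0.114])


def _to_gray(frame: np.ndarray) -> np.ndarray:
    frame = np.asarray(frame)
    if frame.ndim == 3:
        frame = (frame[..., :3].astype(float) @ _LUMA).round()
    return np.clip(frame, 0, 255).astype(np.uint8)


def read_video(source: str | Path) -> Iterator[tuple[int, np.ndarray]]:
    """Yield (index, grayscale frame) from a movie file or a PNG directory.

    Image-sequence directories are read in sorted filename order (use
    zero-padded numeric names).  Re-reading a source yields bit-identical
    frames.
    """
    src = Path(source)
    if src.is_dir():
        files = sorted(
            p for p in src.iterdir() if p.suffix.lower() in (".png", ".tif", ".tiff")
        )
        if not files:
            raise FileNotFoundError(f"no image frames found in {src}")
        import imageio.v3 as iio

        for i, f in enumerate(files):
            yield i, _to_gray(iio.imread(f))
        return
    if not src.exists():
        raise FileNotFoundError(f"video source {src} does not exist")
    import imageio.v3 as iio

    try:
        for i, frame in enumerate(iio.imiter(src)):
            yield i, _to_gray(frame)
    except Exception as exc:  # unreadable container
        raise IOError(f"could not read video container {src}: {exc}") from exc


@dataclass
class PipelineConfig:
    """Tracking-pipeline configuration; keys mirror the tracker properties."""

    frame_rate: float = 332.0
    n_fish: int = 1
    px_per_mm: float = 1.0
    seed: int = 0
    pixel_search: str = "lightest"
    noise_threshold: float = 0.0
    threshold_value: float = 40.0
    threshold_type: str = "binary"
    centroid_method: str = "largest_binary_region"
    min_area: float = 3.0
    max_area: float = 1e9
    tail: TailFitConfig = field(default_factory=TailFitConfig)
    bout_threshold: float = 0.1
    peak_threshold: float = 0.05
    frame_window: int | None = None

    def __post_init__(self) -> None:
        if self.px_per_mm <= 0:
            raise ValueError("px_per_mm scale must be positive")
        if self.n_fish < 1:
            raise ValueError("n_fish must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        tail = TailFitConfig(**raw.pop("tail", {}))
        return cls(tail=tail, **raw)


def _multi_centroids(fg: np.ndarray, cfg: PipelineConfig) -> np.ndarray:
    from skimage.measure import label, regionprops

    mask = fg > cfg.threshold_value
    regions = [
        r
        for r in regionprops(label(mask, connectivity=2))
        if cfg.min_area <= r.area <= cfg.max_area
    ]
    regions.sort(key=lambda r: -r.area)
    return np.array([(r.centroid[1], r.centroid[0]) for r in regions[: cfg.n_fish]])


def track_video(
    source: str | Path, cfg: PipelineConfig, out_dir: str | Path
) -> dict[str, Path]:
    """Run the full offline tracking pipeline and write CSV outputs.

    Two passes: the first builds the running-extremum background, the second
    subtracts it and runs centroid, tail-point, curvature and bout-detection
    stages per frame.  For multi-fish configs, per-frame centroids feed the
    identity assignment and the tail is fitted per identity.  Returns the
    paths of the written CSVs.  Deterministic: same source, config and seed
    give byte-identical outputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bg = BackgroundModel(cfg.pixel_search, cfg.noise_threshold)
    n_frames = 0
    for _, frame in read_video(source):
        bg.update(frame)
        n_frames += 1
    if n_frames == 0:
        raise ValueError(f"no frames in {source}")

    n_pts = cfg.tail.num_tail_segments + 2
    detectors = [
        BoutDetector(cfg.bout_threshold, cfg.peak_threshold, cfg.frame_rate, cfg.frame_window)
        for _ in range(cfg.n_fish)
    ]
    headings = [HeadingTracker() for _ in range(cfg.n_fish)]
    centroid_rows: list[np.ndarray] = []
    tail_rows = []
    kin_rows = []
    for idx, frame in read_video(source):
        fg = bg.subtract(frame)
        try:
            if cfg.n_fish == 1:
                c = calculate_centroid(
                    fg,
                    cfg.threshold_value,
                    cfg.threshold_type,
                    cfg.centroid_method,
                    cfg.min_area,
                    cfg.max_area,
                )
                cents = (
                    np.empty((0, 2)) if c is None else np.array([[c.x, c.y]])
                )
            else:
                cents = _multi_centroids(fg, cfg)
        except Exception as exc:
            log.warning("frame %d: centroid stage failed: %s", idx, exc)
            cents = np.empty((0, 2))
        centroid_rows.append(cents)
        for fish in range(cfg.n_fish):
            t = idx / cfg.frame_rate
            row = {"frame": idx, "t": t, "fish": fish}
            krow = dict(row)
            try:
                if fish >= len(cents):
                    raise ValueError("no centroid detected")
                pts = calculate_tail_points(fg, cents[fish], cfg.tail)
                theta = calculate_tail_curvature(pts)
                ang = tail_angle(theta)
                kin = detectors[fish].update(ang)
                heading = headings[fish].update(tail_points=pts)
                for i, (x, y) in enumerate(pts):
                    row[f"x{i}"] = x
                    row[f"y{i}"] = y
                krow.update(
                    tail_angle=ang,
                    heading=heading,
                    bout=kin.bout_instance,
                    tbf=kin.frequency,
                    amplitude=kin.amplitude,
                )
                for i, th in enumerate(theta, start=1):
                    krow[f"theta{i}"] = th
            except Exception as exc:
                log.warning("frame %d fish %d: %s", idx, fish, exc)
                for i in range(n_pts):
                    row.setdefault(f"x{i}", math.nan)
                    row.setdefault(f"y{i}", math.nan)
                krow.setdefault("tail_angle", math.nan)
            tail_rows.append(row)
            kin_rows.append(krow)

    paths = {
        "tail_points": out / "tail_points.csv",
        "kinematics": out / "kinematics.csv",
    }
    pd.DataFrame(tail_rows).to_csv(paths["tail_points"], index=False)
    pd.DataFrame(kin_rows).to_csv(paths["kinematics"], index=False)
    if cfg.n_fish > 1:
        frames, discard = track_identities(centroid_rows, expected=cfg.n_fish)
        id_rows = []
        for fr, drop in zip(frames, discard):
            for i, (x, y) in sorted(fr.positions.items()):
                id_rows.append(
                    {
                        "frame": fr.frame,
                        "id": i,
                        "x": x,
                        "y": y,
                        "contact": bool(fr.contact.get(i, False)),
                        "discard": bool(drop),
                    }
                )
        paths["identities"] = out / "identities.csv"
        pd.DataFrame(id_rows).to_csv(paths["identities"], index=False)
    return paths
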