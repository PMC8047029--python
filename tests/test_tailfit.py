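"""Circle rasterization and iterative tail-point fitting."""

import math

import numpy as np
import pytest

from zebtrack import synthetic
from zebtrack.tailfit import TailFitConfig, calculate_tail_points, precompute_circle_points

from conftest import polyline_rms, random_pose


class TestCirclePoints:
    def test_radius_one_is_neighborhood_ring(self):
        pts, _ = precompute_circle_points(1)
        as_set = {tuple(p) for p in pts}
        assert as_set <= {(1, 0), (0, 1), (-1, 0), (0, -1), (1, 1), (1, -1), (-1, 1), (-1, -1)}
        assert {(1, 0), (0, 1), (-1, 0), (0, -1)} <= as_set

    @pytest.mark.parametrize("radius", [2, 5, 9, 15])
    def test_points_within_half_pixel_of_ideal_circle(self, radius):
        pts, _ = precompute_circle_points(radius)
        r = np.hypot(pts[:, 0], pts[:, 1])
        assert np.all(np.abs(r - radius) <= 0.5)

    def test_angles_strictly_increasing(self):
        _, angles = precompute_circle_points(8)
        assert np.all(np.diff(angles) > 0)

    def test_radius_below_one_rejected(self):
        with pytest.raises(ValueError):
            precompute_circle_points(0)


class TestCalculateTailPoints:
    def test_output_length_contract(self, rng):
        pose = random_pose(rng)
        frame, truth = synthetic.render_fish_frame(pose, (200, 200))
        for n in (1, 4, 9):
            cfg = TailFitConfig(
                dist_tail_base=7, dist_tail_points=7, num_tail_segments=n,
                heading_direction=pose.heading % (2 * np.pi),
            )
            pts = calculate_tail_points(frame, truth.centroid, cfg)
            assert pts.shape == (n + 2, 2)

    def test_straight_tail_recovered_collinear(self):
        pose = synthetic.FishPose(
            centroid=(60.0, 100.0), heading=np.pi, segment_angles=(0.0,) * 8
        )
        frame, truth = synthetic.render_fish_frame(pose, (200, 200))
        cfg = TailFitConfig(
            dist_tail_base=7, dist_tail_points=7, num_tail_segments=7,
            heading_direction=np.pi, method="pixel_search",
        )
        pts = calculate_tail_points(frame, truth.centroid, cfg)
        assert np.all(np.abs(pts[:, 1] - 100.0) <= 1.5)
        spacing = np.hypot(*np.diff(pts[1:], axis=0).T)
        assert np.all(np.abs(spacing - 7.0) <= 1.5)

    @pytest.mark.parametrize("method", ["pixel_search", "weighted_median", "center_of_mass"])
    def test_curved_tail_all_methods_within_rms(self, method, rng):
        pose = random_pose(rng)
        frame, truth = synthetic.render_fish_frame(pose, (200, 200))
        cfg = TailFitConfig(
            dist_tail_base=7, dist_tail_points=7, num_tail_segments=7,
            heading_direction=pose.heading % (2 * np.pi), method=method,
        )
        pts = calculate_tail_points(frame, truth.centroid, cfg)
        assert polyline_rms(pts[1:], truth.polyline) <= 2.0

    def test_uniform_image_deterministic(self):
        frame = np.full((100, 100), 128, np.uint8)
        cfg = TailFitConfig(dist_tail_base=5, dist_tail_points=5, num_tail_segments=3)
        a = calculate_tail_points(frame, (50.0, 50.0), cfg)
        b = calculate_tail_points(frame, (50.0, 50.0), cfg)
        assert np.array_equal(a, b)

    def test_missing_centroid_propagates(self):
        frame = np.zeros((50, 50), np.uint8)
        assert calculate_tail_points(frame, None, TailFitConfig()) is None

    def test_rotation_equivariance_90deg(self, rng):
        pose = synthetic.FishPose(
            centroid=(100.0, 100.0), heading=np.pi,
            segment_angles=tuple(rng.normal(0, 0.1, 6)),
        )
        frame, truth = synthetic.render_fish_frame(pose, (200, 200))
        cfg = TailFitConfig(
            dist_tail_base=7, dist_tail_points=7, num_tail_segments=5,
            heading_direction=np.pi,
        )
        pts = calculate_tail_points(frame, truth.centroid, cfg)
        # rotate frame 90 deg counterclockwise on screen (np.rot90)
        rot = np.rot90(frame).copy()
        h = frame.shape[1]
        cfg_rot = TailFitConfig(
            dist_tail_base=7, dist_tail_points=7, num_tail_segments=5,
            heading_direction=(np.pi + np.pi / 2) % (2 * np.pi),
        )
        cx, cy = truth.centroid
        pts_rot = calculate_tail_points(rot, (cy, h - 1 - cx), cfg_rot)
        expected = np.stack([pts[:, 1], h - 1 - pts[:, 0]], axis=1)
        assert np.all(np.hypot(*(pts_rot - expected).T) <= 1.5)

    def test_never_doubles_back(self, rng):
        pose = random_pose(rng)
        frame, truth = synthetic.render_fish_frame(pose, (200, 200))
        cfg = TailFitConfig(
            dist_tail_base=7, dist_tail_points=7, num_tail_segments=7,
            range_tail_point_angles=2 * math.pi / 3,
            heading_direction=pose.heading % (2 * np.pi),
        )
        pts = calculate_tail_points(frame, truth.centroid, cfg)
        seg = np.diff(pts[1:], axis=0)
        ang = np.arctan2(seg[:, 1], seg[:, 0])
        turn = np.abs((np.diff(ang) + np.pi) % (2 * np.pi) - np.pi)
        assert np.all(turn <= math.pi / 3 + 0.35)  # arc half-range + rasterization

    def test_weighted_median_jitter_not_worse_than_pixel_search(self, rng):
        # realistic tail width (~5 px stroke) and sensor noise (sd 12)
        pose = synthetic.FishPose(
            centroid=(100.0, 100.0), heading=0.5,
            segment_angles=tuple(rng.normal(0, 0.1, 6)),
            stroke_sigma=2.0,
        )
        frame, truth = synthetic.render_fish_frame(pose, (200, 200))
        jitter = {}
        for method in ("pixel_search", "weighted_median"):
            cfg = TailFitConfig(
                dist_tail_base=7, dist_tail_points=7, num_tail_segments=5,
                heading_direction=pose.heading % (2 * np.pi), method=method,
            )
            tips = []
            for i in range(60):
                noisy = np.clip(
                    frame.astype(float)
                    + np.random.default_rng(i).normal(0, 12, frame.shape),
                    0, 255,
                ).astype(np.uint8)
                pts = calculate_tail_points(noisy, truth.centroid, cfg)
                tips.append(pts[1:])
            tips = np.array(tips)
            jitter[method] = float(tips.std(axis=0).mean())
        assert jitter["weighted_median"] <= jitter["pixel_search"] + 1e-9
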