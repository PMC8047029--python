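"""Curvature math, angle normalization, bout detection, heading tracking."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from zebtrack import kinematics as kin
from zebtrack import synthetic
from zebtrack.blobs import EyeRegion
from zebtrack.synthetic import SwimBout, SwimTraceSpec


class TestTailCurvature:
    def test_collinear_points_zero_curvature(self):
        pts = np.array([[0, 0], [1, 1], [2, 2], [3, 3]], float)
        assert np.allclose(kin.calculate_tail_curvature(pts), 0.0)

    def test_hand_derived_rotation_example(self):
        # theta_h = -pi/2; rotated points [(0,0),(1,0),(2,0),(3,-1)]
        pts = np.array([[0, 0], [0, 1], [0, 2], [1, 3]], float)
        theta = kin.calculate_tail_curvature(pts)
        assert np.allclose(theta, [0.0, 0.0, -np.pi / 4], atol=1e-9)

    def test_global_rotation_invariance(self, rng):
        pts = rng.normal(0, 5, (6, 2)).cumsum(axis=0)
        theta = kin.calculate_tail_curvature(pts)
        a = rng.uniform(0, 2 * np.pi)
        rot = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
        moved = pts @ rot.T + np.array([13.0, -4.0])
        theta2 = kin.calculate_tail_curvature(moved)
        assert np.allclose(theta, theta2, atol=1e-9)

    def test_coincident_points_rejected(self):
        pts = np.array([[0, 0], [1, 0], [1, 0], [2, 0]], float)
        with pytest.raises(ValueError, match="coincident"):
            kin.calculate_tail_curvature(pts)

    def test_first_angle_always_zero(self, rng):
        for _ in range(10):
            pts = rng.normal(0, 4, (5, 2)).cumsum(axis=0)
            theta = kin.calculate_tail_curvature(pts)
            assert theta[0] == pytest.approx(0.0, abs=1e-12)


class TestUnwrap:
    def test_hand_example(self):
        out = kin.unwrap_curvature(np.array([0.0, 3.04, -3.04]))
        assert np.allclose(out, [0.0, 3.04, -3.04 + 2 * np.pi], atol=1e-9)

    def test_smooth_array_unchanged(self):
        arr = np.linspace(0, 1, 10)
        assert np.array_equal(kin.unwrap_curvature(arr), arr)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-10, 10), min_size=1, max_size=20))
    def test_idempotent_and_bounded_steps(self, values):
        arr = np.array(values)
        once = kin.unwrap_curvature(arr)
        assert np.all(np.abs(np.diff(once)) <= np.pi + 1e-12)
        assert np.allclose(kin.unwrap_curvature(once), once)


class TestTailAngle:
    def test_mean_of_last_three(self):
        assert kin.tail_angle(np.array([0.0, 0.1, 0.2, 0.3])) == pytest.approx(0.2)
        assert kin.tail_angle(np.zeros(4)) == 0.0

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            kin.tail_angle(np.array([0.1, 0.2]))


class TestBoutDetector:
    def test_flat_trace_never_bouts(self):
        det = kin.detect_tail_beat(np.zeros(500), 0.1, 0.05, 332.0)
        assert not det["bout"].any()
        assert np.all(det["frequency"] == 0)

    def test_subthreshold_oscillation_never_bouts(self):
        t = np.arange(1000) / 332.0
        angles = 0.05 * np.sin(2 * np.pi * 20.0 * t)
        det = kin.detect_tail_beat(angles, 0.1, 0.05, 332.0)
        assert not det["bout"].any()

    def test_bout_detected_within_half_cycle(self):
        spec = SwimTraceSpec(
            fps=332.0, duration=3.0,
            bouts=(SwimBout(1.0, 1.0, 20.0, 0.5),),
        )
        tr = synthetic.generate_swim_trace(spec)
        det = kin.detect_tail_beat(tr["angle"], 0.1, 0.05, 332.0)
        onset = np.flatnonzero(det["bout"])[0]
        assert 332 <= onset <= 332 + 332.0 / 20.0 / 2.0

    @pytest.mark.parametrize("freq", [5.0, 10.0, 20.0, 30.0])
    def test_frequency_within_quantization_bound(self, freq):
        fps = 332.0
        spec = SwimTraceSpec(
            fps=fps, duration=6.0, bouts=(SwimBout(1.0, 4.0, freq, 0.5),)
        )
        tr = synthetic.generate_swim_trace(spec)
        det = kin.detect_tail_beat(tr["angle"], 0.1, 0.05, fps)
        steady = det["frequency"][int(2 * fps) : int(4.5 * fps)]
        steady = steady[steady > 0]
        period = fps / freq
        bound = max(fps / math.floor(period) - freq, freq - fps / math.ceil(period))
        assert abs(steady.mean() - freq) <= bound

    def test_amplitude_tracks_signed_peak(self):
        fps = 332.0
        spec = SwimTraceSpec(
            fps=fps, duration=3.0, bouts=(SwimBout(0.5, 2.0, 10.0, 0.6),)
        )
        tr = synthetic.generate_swim_trace(spec)
        det = kin.detect_tail_beat(tr["angle"], 0.1, 0.05, fps)
        amps = det["amplitude"][det["amplitude"] != 0]
        assert amps.max() == pytest.approx(0.6, abs=0.02)
        assert amps.min() == pytest.approx(-0.6, abs=0.02)

    def test_detector_resets_after_window(self):
        fps = 332.0
        spec = SwimTraceSpec(
            fps=fps, duration=4.0, bouts=(SwimBout(0.5, 0.5, 20.0, 0.5),)
        )
        tr = synthetic.generate_swim_trace(spec)
        det = kin.detect_tail_beat(tr["angle"], 0.1, 0.05, fps)
        tail = det["bout"][-int(fps):]
        assert not tail.any()
        assert np.all(det["frequency"][-int(fps):] == 0)
        assert np.all(det["amplitude"][-int(fps):] == 0)

    def test_noise_free_interval_count_matches_truth(self):
        fps = 332.0
        spec = SwimTraceSpec(
            fps=fps, duration=8.0,
            bouts=(
                SwimBout(1.0, 0.6, 20.0, 0.5),
                SwimBout(3.5, 0.6, 10.0, 0.4),
                SwimBout(6.0, 0.6, 15.0, 0.5),
            ),
        )
        tr = synthetic.generate_swim_trace(spec)
        det = kin.detect_tail_beat(tr["angle"], 0.1, 0.05, fps)
        intervals = kin.segment_bouts(det["bout"], fps)
        assert len(intervals) == 3

    def test_nonfinite_angle_rejected(self):
        det = kin.BoutDetector(0.1, 0.05, 332.0)
        with pytest.raises(ValueError):
            det.update(float("nan"))


class TestSegmentBouts:
    def test_empty_flags(self):
        assert kin.segment_bouts(np.zeros(100, bool), 332.0) == []

    def test_padding_five_frames_at_332fps(self):
        flags = np.zeros(300, bool)
        flags[100:200] = True  # frames 100..199
        (iv,) = kin.segment_bouts(flags, 332.0)
        assert iv == (95, 205)  # round(0.015*332) = 5 each side, half-open

    def test_nearby_runs_merge_after_padding(self):
        flags = np.zeros(100, bool)
        flags[10:20] = True
        flags[22:30] = True  # 2 frames apart, pad 5 -> overlap
        assert kin.segment_bouts(flags, 332.0) == [(5, 35)]

    def test_clipped_to_record(self):
        flags = np.ones(20, bool)
        assert kin.segment_bouts(flags, 332.0) == [(0, 20)]


class TestBoutFeatures:
    def test_constant_zero(self):
        f = kin.compute_bout_features(np.zeros(50), np.zeros(50), (0, 50), 332.0)
        assert (f.integral, f.sd, f.max_amplitude) == (0.0, 0.0, 0.0)
        assert f.mean_tbf == 0.0

    def test_constant_angle_integral(self):
        angles = np.full(332, 0.2)
        f = kin.compute_bout_features(angles, np.zeros(332), (0, 332), 332.0)
        assert f.integral == pytest.approx(0.2, rel=1e-12)

    def test_symmetric_sine_cancels_integral_not_sd(self):
        t = np.arange(332) / 332.0
        angles = 0.5 * np.sin(2 * np.pi * 10.0 * t)
        f = kin.compute_bout_features(angles, np.zeros(332), (0, 332), 332.0)
        assert abs(f.integral) < 1e-3
        assert f.sd > 0.3 and abs(f.max_amplitude) > 0.49

    def test_mean_tbf_ignores_zeros(self):
        tbf = np.array([0.0, 0.0, 20.0, 22.0, 0.0])
        f = kin.compute_bout_features(np.zeros(5), tbf, (0, 5), 100.0)
        assert f.mean_tbf == pytest.approx(21.0)

    def test_interval_outside_record_rejected(self):
        with pytest.raises(ValueError):
            kin.compute_bout_features(np.zeros(10), np.zeros(10), (5, 15), 100.0)


def _eye(orientation, major=10.0):
    return EyeRegion((0.0, 0.0), 10.0, major, orientation, "left")


class TestEyeAngles:
    def test_aligned_with_heading_is_zero(self):
        (a, b) = kin.calculate_eye_angles((_eye(0.3), _eye(0.3)), theta_h=-0.3)
        assert a == pytest.approx(0.0, abs=1e-12)

    def test_printed_equation_example(self):
        (a, _) = kin.calculate_eye_angles((_eye(np.pi / 4), _eye(0.0)), theta_h=0.0)
        assert a == pytest.approx(np.pi / 4)

    def test_pi_disambiguation_into_half_range(self):
        (a, _) = kin.calculate_eye_angles((_eye(np.pi * 0.9), _eye(0.0)), theta_h=0.0)
        assert -np.pi / 2 < a <= np.pi / 2
        assert a == pytest.approx(np.pi * 0.9 - np.pi)

    def test_invariant_to_axis_length(self):
        a1 = kin.calculate_eye_angles((_eye(0.7, 5.0), _eye(0.7, 5.0)), 0.2)
        a2 = kin.calculate_eye_angles((_eye(0.7, 50.0), _eye(0.7, 50.0)), 0.2)
        assert a1 == pytest.approx(a2)


class TestHeadingTracker:
    def test_symmetric_eyes_give_zero_heading(self):
        eyes = (
            EyeRegion((10.0, 4.0), 5, 3, 0.0, "left"),
            EyeRegion((10.0, -4.0), 5, 3, 0.0, "right"),
        )
        tr = kin.HeadingTracker()
        assert tr.update(eyes=eyes, centroid=(0.0, 0.0)) == pytest.approx(0.0)

    def test_cumulative_rotation_720_degrees(self):
        tr = kin.HeadingTracker()
        step = math.radians(10.0)
        for i in range(73):  # 72 increments of 10 deg
            h = i * step
            pts = np.array(
                [[0.0, 0.0], [-10.0 * math.cos(h), 10.0 * math.sin(h)]]
            )  # tail opposite heading (image y down)
            out = tr.update(tail_points=pts)
        assert out == pytest.approx(math.radians(720.0))

    def test_initialize_to_zero(self):
        tr = kin.HeadingTracker(initialize_to_zero=True)
        pts = np.array([[0.0, 0.0], [-3.0, 8.0]])
        assert tr.update(tail_points=pts) == 0.0


class TestCleanHeading:
    def test_smooth_trace_unchanged(self):
        s = np.linspace(0, 2.0, 500)
        out = kin.clean_heading_trace(s, 332.0)
        assert np.allclose(out, s)

    def test_injected_jump_removed_and_offset(self):
        # flat trace so the removed span carries no genuine drift: the
        # excision oracle is then exact
        fps = 332.0
        s = np.full(400, 0.3)
        corrupted = s.copy()
        corrupted[200:] += 2 * np.pi  # 360 deg jump over one frame
        out = kin.clean_heading_trace(corrupted, fps)
        good = ~np.isnan(out)
        assert np.isnan(out).any()
        # oracle: re-adding the offset after the gap reproduces the input
        restored = out.copy()
        restored[200:] += 2 * np.pi
        assert np.allclose(restored[good], corrupted[good], atol=1e-9)
        assert np.all(np.abs(np.diff(out[good])) < 0.1)

    def test_drifting_trace_stays_continuous_after_cleanup(self):
        fps = 332.0
        s = np.linspace(0, 1.0, 400)
        corrupted = s.copy()
        corrupted[200:] += 2 * np.pi
        out = kin.clean_heading_trace(corrupted, fps)
        good = ~np.isnan(out)
        assert np.all(np.abs(np.diff(out[good])) < 0.1)

    def test_consecutive_artifacts_compose(self):
        fps = 332.0
        s = np.full(600, -0.5)
        corrupted = s.copy()
        corrupted[200:] += 2 * np.pi
        corrupted[400:] -= 2 * np.pi
        out = kin.clean_heading_trace(corrupted, fps)
        good = ~np.isnan(out)
        assert np.all(np.abs(np.diff(out[good])) < 0.1)
        assert out[good][-1] == pytest.approx(s[-1], abs=1e-9)
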