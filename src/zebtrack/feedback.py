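"""Closed-loop optomotor feedback: 1-D vigor-based and 2-D orientation-based.

In the one-dimensional head-fixed assay the grating's velocity is the
baseline velocity minus the swim vigor scaled by a gain factor,

    V_S(t) = V_B - gain * vigor_scale * vigor(t),

where the vigor is the magnitude of the tail-angle derivative averaged over
a short window (15 ms) with an exponential decay (time constant 9 ms) and
gated by the bout-instance signal, emulating burst-and-glide acceleration.
``vigor_scale`` is calibrated numerically, once per (frame rate, window,
decay) combination, so that a sustained reference bout with a 20 Hz tail
beat corresponds to a 20 mm/s forward translation at gain 1; with a 10 mm/s
baseline this yields the canonical steady-state stimulus velocities of
-10, 0 and -20 mm/s at gains 1.0, 0.5 and 1.5.

In the two-dimensional assay the velocity along the drift axis is driven by
a boxcar-averaged tail-beat frequency and attenuated by the stimulus
orientation relative to the heading,

    V_S(t) = V_B - boxcar(F)(t) * gain * (1 - |theta| / 90),

with theta in degrees wrapped to [-180, 180); note the attenuation factor is
continuous inside the range but jumps at the wrap point itself (|theta| is
1 at +/-90 deg and -1 as theta approaches +/-180 deg).  The stimulus
angular velocity is the mean tail curvature divided by the time since bout
onset, so early bout curvature turns the stimulus most.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .kinematics import detect_tail_beat
from .synthetic import SwimBout, SwimTraceSpec, generate_swim_trace

__all__ = [
    "FeedbackConfig1D",
    "FeedbackConfig2D",
    "calibrate_vigor_scale",
    "gain_schedule",
    "run_trial_1d",
    "stimulus_angular_velocity",
    "stimulus_velocity_1d",
    "stimulus_velocity_2d",
    "swim_vigor",
]

REFERENCE_TBF_HZ = 20.0
REFERENCE_TRANSLATION_MM_S = 20.0


@dataclass(frozen=True)
class FeedbackConfig1D:
    """One-dimensional closed-loop configuration.

    ``window_s`` and ``decay_s`` are the vigor integration window and the
    exponential decay time constant; ``vigor_scale`` converts vigor units to
    mm/s and is usually filled in by :func:`calibrate_vigor_scale`.
    ``signed_vigor`` switches the tail-angle derivative from magnitude
    (default; a bout slows the grating regardless of beat direction) to its
    signed value.
    """

    frame_rate: float
    baseline_velocity: float = 10.0
    gain: float = 1.0
    window_s: float = 0.015
    decay_s: float = 0.009
    vigor_scale: float | None = None
    signed_vigor: bool = False

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.decay_s <= 0:
            raise ValueError("decay time constant must be positive")
        if self.window_frames < 1:
            raise ValueError("vigor window must span at least one frame")

    @property
    def window_frames(self) -> int:
        return max(1, int(round(self.window_s * self.frame_rate)))


def swim_vigor(
    angles: np.ndarray, bout_flags: np.ndarray, cfg: FeedbackConfig1D
) -> np.ndarray:
    """Per-frame swim vigor (1/s): windowed, decayed tail-angle derivative.

    The per-frame derivative dT/dt (rad/s, magnitude unless
    ``cfg.signed_vigor``) is averaged over the last ``window_frames`` frames
    with weights ``exp(-dt / decay_s)`` and gated by the bout-instance
    signal: vigor is identically zero outside detected bouts.
    """
    angles = np.asarray(angles, float)
    flags = np.asarray(bout_flags, bool)
    if angles.shape != flags.shape:
        raise ValueError("angle and bout-flag arrays must have equal length")
    n = cfg.window_frames
    dt = 1.0 / cfg.frame_rate
    deriv = np.gradient(angles, dt)
    if not cfg.signed_vigor:
        deriv = np.abs(deriv)
    weights = np.exp(-np.arange(n) * dt / cfg.decay_s)
    padded = np.concatenate([np.zeros(n - 1), deriv])
    windows = np.lib.stride_tricks.sliding_window_view(padded, n)[:, ::-1]
    vigor = windows @ weights / n
    return vigor * flags


def stimulus_velocity_1d(vigor: np.ndarray, cfg: FeedbackConfig1D) -> np.ndarray:
    """V_S = V_B - gain * vigor_scale * vigor (mm/s)."""
    if cfg.vigor_scale is None:
        raise ValueError("vigor_scale not set; run calibrate_vigor_scale first")
    return cfg.baseline_velocity - cfg.gain * cfg.vigor_scale * np.asarray(vigor)


def calibrate_vigor_scale(
    cfg: FeedbackConfig1D,
    reference_tbf: float = REFERENCE_TBF_HZ,
    reference_amplitude: float = 1.0,
    reference_translation: float = REFERENCE_TRANSLATION_MM_S,
) -> FeedbackConfig1D:
    """Solve the vigor-to-velocity scale on a sustained reference bout.

    A unit-amplitude sinusoidal tail beat at ``reference_tbf`` (20 Hz) must
    correspond to ``reference_translation`` (20 mm/s) of forward translation
    at gain 1.  The scale is the ratio of that translation to the mean
    steady-state vigor of the reference bout, measured over an integer
    number of beat cycles.  Returns a copy of ``cfg`` with ``vigor_scale``
    filled in.
    """
    fps = cfg.frame_rate
    cycles = 40
    duration = cycles / reference_tbf + 0.2
    spec = SwimTraceSpec(
        fps=fps,
        duration=duration,
        bouts=(
            SwimBout(
                onset=0.0,
                duration=duration,
                beat_frequency=reference_tbf,
                amplitude=reference_amplitude,
            ),
        ),
    )
    trace = generate_swim_trace(spec)
    vigor = swim_vigor(trace["angle"], np.ones_like(trace["angle"], bool), cfg)
    period = fps / reference_tbf
    start = int(round(5 * period))
    stop = start + int(round(30 * period))
    mean_vigor = float(vigor[start:stop].mean())
    if mean_vigor <= 0:
        raise RuntimeError("reference bout produced zero vigor")
    return replace(cfg, vigor_scale=reference_translation / mean_vigor)


def run_trial_1d(
    angles: np.ndarray,
    cfg: FeedbackConfig1D,
    bout_threshold: float = 0.1,
    peak_threshold: float = 0.05,
    static_s: float = 30.0,
    motion_s: float = 10.0,
    iti_s: float = 30.0,
) -> dict[str, np.ndarray]:
    """Run one closed-loop trial over a tail-angle stream.

    The stream covers static grating, motion period and inter-trial
    interval; the grating is stationary (V_S = 0) outside the motion period
    and follows the feedback equation inside it.  Bout instances come from
    the online detector.  Returns per-frame arrays ``v_s``, ``vigor``,
    ``bout`` and ``t``; the log length equals the stream length.
    """
    angles = np.asarray(angles, float)
    fps = cfg.frame_rate
    n = angles.size
    kin = detect_tail_beat(angles, bout_threshold, peak_threshold, fps)
    vigor = swim_vigor(angles, kin["bout"], cfg)
    v_s = np.asarray(stimulus_velocity_1d(vigor, cfg), float)
    t = np.arange(n) / fps
    motion = (t >= static_s) & (t < static_s + motion_s)
    v_s[~motion] = 0.0
    return {"t": t, "v_s": v_s, "vigor": vigor, "bout": kin["bout"]}


# ---------------------------------------------------------------------------
# two-dimensional feedback
# ---------------------------------------------------------------------------


def _wrap_deg(theta: float) -> float:
    return (theta + 180.0) % 360.0 - 180.0


@dataclass(frozen=True)
class FeedbackConfig2D:
    """Two-dimensional closed-loop configuration.

    ``boxcar_s`` is the moving-average window applied to the tail-beat
    frequency (15 ms by default, paralleling the 1-D vigor window).
    """

    frame_rate: float
    baseline_velocity: float = 10.0
    gain: float = 1.0
    boxcar_s: float = 0.015

    @property
    def boxcar_frames(self) -> int:
        return max(1, int(round(self.boxcar_s * self.frame_rate)))


def stimulus_velocity_2d(
    tbf_history: np.ndarray, theta_deg: float, cfg: FeedbackConfig2D
) -> float:
    """V_S = V_B - boxcar(F) * gain * (1 - |theta| / 90), theta in degrees."""
    theta = _wrap_deg(theta_deg)
    f = np.asarray(tbf_history, float)
    n = min(cfg.boxcar_frames, f.size)
    boxcar = float(f[-n:].mean()) if n else 0.0
    return cfg.baseline_velocity - boxcar * cfg.gain * (1.0 - abs(theta) / 90.0)


def stimulus_angular_velocity(
    curvature: np.ndarray, t: float, t_0: float
) -> float:
    """V_theta = mean tail curvature / (t - t_0), rad per unit time.

    Strictly decreasing in time since bout onset, so the initial bend of a
    bout reorients the stimulus the most.
    """
    if t <= t_0:
        raise ValueError("t must be after bout onset t_0")
    return float(np.mean(np.asarray(curvature, float))) / (t - t_0)


# ---------------------------------------------------------------------------
# gain schedule
# ---------------------------------------------------------------------------

_BLOCK = (1.0, 1.0, 1.0, 0.5, 0.5, 0.5, 1.5, 1.5, 1.5, 1.0, 1.0, 1.0, 1.5, 1.5, 1.5, 0.5, 0.5, 0.5)


def gain_schedule(trial_index: int) -> float:
    """Gain factor for a 0-based trial index in the 54-trial protocol.

    Trials run in triplets: medium, low, high for the first nine trials,
    then medium, high, low for the next nine; the 18-trial block repeats
    three times.
    """
    if not 0 <= trial_index < 54:
        raise ValueError("trial_index must be in [0, 54)")
    return _BLOCK[trial_index % 18]
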