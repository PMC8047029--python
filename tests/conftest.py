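import numpy as np
import pytest

from zebtrack import synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_pose(rng, with_eyes=False, frame_size=(200, 200), n_segments=8):
    """A random but renderable fish pose centered in the frame."""
    h, w = frame_size
    heading = float(rng.uniform(0.0, 2.0 * np.pi))
    pose = synthetic.FishPose(
        centroid=(w / 2 + rng.uniform(-15, 15), h / 2 + rng.uniform(-15, 15)),
        heading=heading,
        segment_angles=tuple(rng.normal(0.0, 0.12, n_segments)),
    )
    if with_eyes:
        pose = synthetic.FishPose(
            centroid=pose.centroid,
            heading=pose.heading,
            segment_angles=pose.segment_angles,
            eyes=synthetic.default_eyes(pose.centroid, pose.heading),
        )
    return pose


def polyline_rms(points, polyline):
    """RMS distance from fitted points to a densely resampled polyline."""
    dense = []
    for p0, p1 in zip(polyline[:-1], polyline[1:]):
        t = np.linspace(0.0, 1.0, 50)[:, None]
        dense.append(p0 * (1 - t) + p1 * t)
    dense = np.vstack(dense)
    d = np.sqrt(((points[:, None, :] - dense[None, :, :]) ** 2).sum(-1)).min(1)
    return float(np.sqrt((d**2).mean()))
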