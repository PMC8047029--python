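"""Multi-animal identity assignment, contact handling and accuracy reporting.

Identities are propagated frame to frame by solving a linear sum assignment
on the Euclidean distance matrix between the previous and current centroids.
When fish touch, their blobs merge and fewer centroids are detected than
expected; each unassigned previous identity is then mapped to its nearest
current centroid and every identity sharing that centroid is flagged as a
contact.  Contact flags feed a per-frame discard mask, and the overall
accuracy of a record is the percentage of tracked data points free of
contacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

__all__ = [
    "IdentityFrame",
    "TrackingAccuracyReport",
    "area_contact_flags",
    "assign_identities",
    "group_omr_direction",
    "percent_accuracy",
    "track_identities",
]


@dataclass
class IdentityFrame:
    """Per-frame identity map: id -> centroid, plus per-id contact flags."""

    frame: int
    positions: dict[int, tuple[float, float]]
    contact: dict[int, bool] = field(default_factory=dict)
    lost: bool = False

    def __post_init__(self) -> None:
        if not self.contact:
            self.contact = {i: False for i in self.positions}


def assign_identities(
    prev: IdentityFrame, centroids: np.ndarray, frame: int | None = None
) -> IdentityFrame:
    """Assign current centroids to the previous frame's identities.

    The assignment minimizes the total Euclidean distance between paired
    centroids.  With fewer current centroids than identities (merged blobs),
    each unassigned identity keeps tracking its nearest current centroid and
    every identity sharing a centroid is contact-flagged.  With zero current
    centroids the previous positions are carried over and the frame is
    marked lost.
    """
    frame = prev.frame + 1 if frame is None else frame
    ids = sorted(prev.positions)
    cur = np.asarray(centroids, float).reshape(-1, 2)
    if cur.shape[0] == 0:
        return IdentityFrame(
            frame,
            dict(prev.positions),
            {i: True for i in ids},
            lost=True,
        )
    prev_xy = np.array([prev.positions[i] for i in ids], float)
    cost = cdist(prev_xy, cur)
    rows, cols = linear_sum_assignment(cost)
    positions: dict[int, tuple[float, float]] = {}
    assigned_col: dict[int, int] = {}
    for r, c in zip(rows, cols):
        positions[ids[r]] = (float(cur[c, 0]), float(cur[c, 1]))
        assigned_col[ids[r]] = int(c)
    unassigned = [i for i in ids if i not in positions]
    for i in unassigned:
        c = int(np.argmin(cost[ids.index(i)]))
        positions[i] = (float(cur[c, 0]), float(cur[c, 1]))
        assigned_col[i] = c
    contact = {i: False for i in ids}
    if unassigned:
        col_users: dict[int, list[int]] = {}
        for i, c in assigned_col.items():
            col_users.setdefault(c, []).append(i)
        for users in col_users.values():
            if len(users) > 1:
                for i in users:
                    contact[i] = True
    return IdentityFrame(frame, positions, contact)


def track_identities(
    centroids_per_frame: list[np.ndarray],
    expected: int | None = None,
) -> tuple[list[IdentityFrame], np.ndarray]:
    """Run identity assignment over a whole record.

    The first frame seeds identities 0..k-1 in the given centroid order.
    Returns the per-frame identity maps and a per-frame boolean discard mask
    that is true wherever any contact (or a lost frame) occurred.
    """
    if not centroids_per_frame:
        return [], np.zeros(0, bool)
    first = np.asarray(centroids_per_frame[0], float).reshape(-1, 2)
    k = first.shape[0] if expected is None else expected
    state = IdentityFrame(
        0, {i: (float(x), float(y)) for i, (x, y) in enumerate(first[:k])}
    )
    frames = [state]
    discard = np.zeros(len(centroids_per_frame), bool)
    discard[0] = first.shape[0] < k
    for f, cents in enumerate(centroids_per_frame[1:], start=1):
        state = assign_identities(state, cents, frame=f)
        frames.append(state)
        discard[f] = state.lost or any(state.contact.values())
    return frames, discard


def area_contact_flags(
    areas_per_frame: list[np.ndarray], factor: float = 1.8
) -> np.ndarray:
    """Optional contact trigger for overlaps that do not merge centroids.

    Flags a frame when any blob area exceeds ``factor`` times the median
    single-blob area of the record.  Complements the centroid-count trigger
    used by :func:`track_identities`.
    """
    all_areas = np.concatenate([np.atleast_1d(a) for a in areas_per_frame])
    if all_areas.size == 0:
        return np.zeros(len(areas_per_frame), bool)
    limit = factor * float(np.median(all_areas))
    return np.array(
        [np.any(np.atleast_1d(a) > limit) for a in areas_per_frame], bool
    )


@dataclass(frozen=True)
class TrackingAccuracyReport:
    total_tracked_data_points: int
    number_of_contacts: int
    percent_accuracy: float


def percent_accuracy(total: int, contacts: int) -> TrackingAccuracyReport:
    """Percentage of tracked data points free of fish-to-fish contacts:
    ``(total - contacts) / total * 100``."""
    if total <= 0:
        raise ValueError("total tracked data points must be positive")
    pct = 100.0 * (total - contacts) / total
    return TrackingAccuracyReport(int(total), int(contacts), float(pct))


def group_omr_direction(
    centroids: np.ndarray,
    arena_width: float,
    previous: str,
) -> str:
    """Group-level optomotor stimulus direction with hysteresis.

    The group's center of mass is the mean of all centroids.  Entering the
    leftmost quarter of the arena switches the stimulus to move rightward,
    entering the rightmost quarter switches it leftward; anywhere else the
    previous direction persists.
    """
    cur = np.asarray(centroids, float).reshape(-1, 2)
    if cur.shape[0] == 0:
        raise ValueError("need at least one centroid")
    if previous not in ("leftward", "rightward"):
        raise ValueError("previous direction must be 'leftward' or 'rightward'")
    com_x = cur[:, 0].mean()
    if com_x < arena_width / 4.0:
        return "rightward"
    if com_x > 3.0 * arena_width / 4.0:
        return "leftward"
    return previous
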