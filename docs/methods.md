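# Methods

This note records the models implemented in `zebtrack`, the parameter
defaults and why they were chosen, the numerical details that matter, and
what the synthetic-fixture tests do and do not establish about real data.

## Conventions

Images use a top-left origin with x rightward (columns) and y downward
(rows).  Reported angles are counterclockwise-positive mathematical angles;
the conversion happens through the sign flip in the heading equation
θ_h = −atan2(Δy, Δx), so geometry stays in image coordinates and only the
reported quantities flip.  "Left" is the fish's own left: positive signed
bearing relative to the heading in the reporting convention.  The prey-arc
yaw is the one deliberate exception (left = negative), chosen so the yaw
histogram reads like a visual-field axis; it is documented on the function.
All CSVs carry radians, 0-based frame indices and pixel coordinates.

## Background model

Per-pixel running extremum with an optional noise threshold.  Ties do not
update (a strict inequality), and the threshold is applied symmetrically in
darkest mode, mirroring the lightest-mode rule.  The background initializes
to the first frame, so it converges to the true scene exactly once the
subject has vacated each pixel at least once.  Gaussian-mixture or median
background models are out of scope by design — the running extremum is the
method under study.

## Tail-point fitting

Circles of radius `dist_tail_base` and `dist_tail_points` are rasterized
once and cached: for each finely sampled angle, the lattice corner with the
smallest radial error is kept, which bounds every point's distance to the
ideal circle by 0.5 px (at radius 1 this yields the 4-neighborhood ring).
The first tail point is either the contrast extremum over the full base
circle (heading unset, negative sentinel) or the circle point opposite the
supplied heading.  Subsequent points search an arc of total angle
`range_tail_point_angles` (default 120°) centered on the previous segment's
direction, which structurally bounds the bend between successive fitted
segments to half the arc.  For the second point, where only one previous
segment exists, the centroid-to-first-point direction seeds the arc.

Scorers: `pixel_search` takes the extremal pixel; `weighted_median` takes
the arc point at the half-mass of weights w = |I − opposing extremum|
(absolute contrast, so the most fish-like pixels weigh most);
`center_of_mass` takes the arc point nearest the contrast-weighted
centroid.  All three return members of the precomputed point set; ties
break to the first point in arc traversal order.  Offsets (`offset_x/y`)
apply last, to all points.

The weighted-median and center-of-mass scorers are smoother frame to frame
than pixel search when the tail stroke spans several arc points.  With very
thin strokes (≲3 px) and strong noise the weighted median can instead
jitter more, because background pixels carry nonzero contrast weight on
both sides of the stroke; the jitter fixtures therefore render tails at a
realistic ~5 px stroke width (about what a 4 mm larva's tail subtends at
~18 px/mm) with additive sensor noise of sd 12 intensity units.

## Curvature, tail angle, unwrapping

Curvature angles are the bearings between successive tail points after
translating the centroid to the origin and rotating by θ_h, so θ₁ ≡ 0.  The
published description of this computation is ambiguous between
successive-point and point-to-centroid bearings; successive-point
differences are implemented, matching the accompanying prose and the θ₁ = 0
contract.  Unwrapping offsets an angle by 2π whenever it differs from its
(already adjusted) predecessor by more than π, applied iteratively — the
operation is idempotent.  The scalar tail angle is the mean of the last
three curvature values.

## Online bout and tail-beat detection

The detector keeps a ring buffer of `frame_window` recent tail angles with
its running min and max.  A bout starts when the current angle departs from
a window extremum by more than `bout_threshold` (rad); inside a bout the
detector alternates between hunting maxima and minima, registering a peak
(and its signed amplitude) once the angle retreats from the running
extremum by `peak_threshold`.  Frequency is the frame rate divided by the
frame count between successive same-direction peaks, i.e. one full
oscillation cycle, so a 20 Hz sine reads 20 Hz; a `half_cycle_frequency`
switch divides by the opposite-peak spacing instead for users who prefer
the 2× convention.  When `frame_window` frames pass without the bout
threshold re-triggering, the bout ends and frequency and amplitude reset to
0.  A threshold re-trigger inside the expiry window continues the same
bout (continuous swimming is one bout).

`frame_window` defaults to round(0.15 s · frame rate): long enough to
bridge inter-beat intervals down to ~7 Hz, short enough that bouts release
within a few hundred milliseconds.  Detection frequency is quantized by
integer frame counts — at 332 fps a 20 Hz beat alternates between 16- and
17-frame cycles (20.75/19.53 Hz), so steady-state accuracy is assessed
against the bound max(fps/⌊p⌋ − f, f − fps/⌈p⌉), p = fps/f.  The extremum
maintenance is a plain min/max over the buffer; the buffer is ≤ ~50
elements, so the O(n) scan is irrelevant to throughput and simpler than a
monotone deque.

Bout segmentation takes maximal true-runs of the bout flag, pads each by
round(0.015 s · fps) frames on both sides (5 frames at 332 fps), clips to
the record and merges overlaps.  Per-bout features: mean of nonzero
tail-beat-frequency samples, integral Σ angle / fps (signed), standard
deviation, and the signed angle of largest magnitude.  Absolute values of
the integral and max amplitude are taken only at clustering time.

## Eyes and heading

Eye candidates are connected components filtered by area, by distance from
the fish centroid, and by bearing within ±half the search range of the
heading; exactly two survivors are required (the failure carries the
survivor count).  Survivors are first ordered by absolute angular offset
from the heading and then re-ordered by signed bearing — positive (left)
first; the second ordering's key is stated only implicitly in the source
description and signed bearing is the reading adopted.  Major-axis
orientation is computed from second central moments in the y-up frame,
defined modulo π.  The per-eye angle builds a point at distance l_M and
angle θ_M, rotates it by θ_h, and resolves the π ambiguity into
(−π/2, π/2] relative to the heading.

Cumulative heading integrates wrapped frame-to-frame changes of the
instantaneous heading (centroid→eye-midpoint, or tail-base→centroid), so it
is unbounded (a fish circling twice reads 720°).  The cleanup rule for
free-swimming records scans 10 ms spans; a span whose endpoints differ by
more than 180° is excised and all later samples are shifted so the
post-gap value matches the pre-gap value.  Consecutive artifacts compose.
Genuine rotation occurring inside an excised span is eaten by the shift —
inherent to the rule, and why excisions are reported as NaN rather than
interpolated.

## Closed-loop feedback

1-D: vigor is the magnitude of the tail-angle derivative averaged over
n = round(0.015·fps) frames with weights exp(−Δt/9 ms), gated by the bout
instance, and V_S = V_B − gain·scale·vigor.  The printed form of the decay
term in the source description would make 9 a rate; the prose ("decay
constant of 9 ms") is followed, so 9 ms is a time constant.  The magnitude
(not signed) derivative is the default because a bout must slow the grating
regardless of beat direction; `signed_vigor` exposes the alternative.  The
1/n normalization sits outside the exponential weighting as printed — the
choice only rescales the calibrated `vigor_scale`.

`vigor_scale` is solved numerically once per (frame rate, window, decay):
the mean steady-state vigor of a unit-amplitude 20 Hz reference sine,
measured over whole beat cycles, is mapped to 20 mm/s at gain 1.  Because
an integer number of cycles through a linear time-invariant window has an
exact mean, the three canonical gain examples (−10, 0, −20 mm/s at gains
1.0, 0.5, 1.5 against V_B = 10 mm/s) reproduce to ~1e−6 rather than the 2%
the discretization nominally allows.  Note the calibration is
amplitude-specific: vigor is linear in beat amplitude, so "20 Hz ↔
20 mm/s" holds for bouts at the reference amplitude (1 rad here).

2-D: V_S = V_B − boxcar(F)·gain·(1 − |θ|/90) with θ in degrees wrapped to
[−180, 180).  The attenuation factor is continuous inside the range but
jumps from −1 to −1⁺ across the wrap itself (|θ| is symmetric, so the jump
is degenerate; it is still documented because θ = −180 is included and
+180 is not).  The boxcar window defaults to 15 ms to parallel the 1-D
vigor window (unstated in the source).  V_θ = mean(TC)/(t − t₀) makes the
stimulus most sensitive to the initial bend of a bout.  The gain schedule
is the 18-trial block [1.0×3, 0.5×3, 1.5×3, 1.0×3, 1.5×3, 0.5×3] repeated
three times.

## Open-loop stimuli

The looming law θ(t) = 2·atan((l/v)/(t_c − t)) is the standard constant
approach; only l/v (90 ms) is prescribed by the protocol, so the law is
isolated in one function for replacement.  t_c is placed so truncation at
120° occurs 3 s after expansion onset (13 s into a trial with a 10 s static
period); the pre-expansion size is θ at expansion onset, since no static
size is prescribed.  Gratings drift at heading + relative direction about
the centroid with temporal frequency velocity/period (1 Hz at 1 cm/s over
1 cm).  The prey arc φ(t) = 60°·sin((100/60)·t) peaks at 100°/s dead ahead
and stops at ±60°.  Calibration solves the affine camera→display map from
rectangle corners by least squares (exact for rectangles).

## Multi-animal identities

Frame-to-frame assignment minimizes total Euclidean distance
(`scipy.optimize.linear_sum_assignment`; verified against exhaustive
permutation search in tests).  When fewer centroids than identities are
present, each unassigned identity adopts its nearest current centroid and
all sharers of a centroid are contact-flagged; contact and lost frames feed
a discard mask.  The discard window around a merge defaults to the merge
frames themselves (0 frames of margin), configurable by consumers; an
optional area-based trigger (blob area > 1.8× the record's median) catches
overlaps that do not merge centroids.  Percent accuracy is
100·(total − contacts)/total, computed in exactly that operation order.

## Bout clustering

Features are z-scored by default (the Hz-scaled frequency would otherwise
dominate Euclidean distances); linkage is Ward on Euclidean distance —
standard for compact kinematic clusters — with both exposed.  Cluster count
is the argmax of the mean silhouette score over k = 2…10, shrunk with a
warning when there are fewer bouts than k+1.  A record of identical bouts
has no defined silhouette and returns an explicit degenerate result.
J-turn direction uses the sign of the unnormalized bout integral (positive
= left); zero integrals fall to "right" and are flagged.

## Synthetic fixtures

Rendered fish are a hard-edged body disk with Gaussian falloff, two filled
eye ellipses rostral to the centroid, and a tail stroke with Gaussian
cross-section through the ground-truth polyline (anti-aliased, so the
sub-pixel scorers have meaningful contrast).  Swim traces are pure
sinusoids inside scripted bouts plus optional white noise; prey paths are
run/pause/turn state machines with randomized speeds, distances, pauses and
angular velocities, reflecting at arena walls.  All generators take
explicit seeds; nothing uses global random state.

What passing tests show: the geometry, filtering rules and feedback
equations are implemented correctly, and the tracking stack inverts its own
forward model to ≤2 px.  What they do not show: robustness to real optics —
pigment variation, water-surface glare, partial occlusion, defocus, or
tails thinner than ~3 px — nor real-time throughput, which is out of scope
for this offline implementation.

## Problem sizes

The default test and acceptance runs use desk-scale inputs chosen as the
smallest sizes at which each claim is meaningful: 12 s feedback trials at
332 fps (~4,000 frames), 50 random poses for tracking recovery, 100 noise
realizations for jitter, 1,000 random instances for the assignment oracle,
and 20 seeds × 90 bouts for clustering.  The in-vivo numbers of the
original protocol (silhouette 0.65 on 688 real bouts, >90% accuracy over
5–20 fish, 64.1 ms round-trip latency) depend on real recordings and
hardware and are deliberately not reproduced.
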