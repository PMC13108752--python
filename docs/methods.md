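# Methods

This note documents the models, conventions and numerical choices behind
`gesturecap`, and what the synthetic study does and does not establish.

## Problem setting

Optical motion capture (MoCap) is the reference standard for measuring
gesture kinematics in 3D, but it is expensive, space-hungry, and its
retroreflective markers can disturb natural gesturing. Markerless human
pose estimation (HPE) on consumer video offers an alternative: 2D keypoint
detectors per camera, combined either by classical stereo triangulation
(metric, needs two calibrated cameras) or by learned monocular 3D lifting
(single camera, scale-ambiguous, weak in depth). The package quantifies
how close each route gets to a MoCap reference on the 13 upper-body
keypoints that matter for gesture research, and how well the reconstructed
*gesture space* (the volume the wrists visit) matches.

## Camera model and triangulation

Cameras are pinhole models with the 5-coefficient radial–tangential
distortion (k1, k2, p1, p2, k3) used by checkerboard calibration tooling.
The world frame is the reference camera's frame (R = I, t = 0); all other
extrinsics are relative to it. Units are millimetres; pixels have their
origin at the top-left corner, u rightward, v downward; frame indices are
0-based. Calibration *estimation* is out of scope: parameter files are
loaded, validated (orthonormal rotation, det +1, tolerance 1e-9), and can
be sanity-checked with the re-projection RMS operation.

Undistortion has no closed form; a fixed-point iteration runs at most 20
sweeps or until the update drops below 1e-12 — far beyond detector
precision for realistic distortion magnitudes.

Triangulation is plain linear DLT on undistorted normalized coordinates:
the two-view homogeneous system `A X = 0` (4×4) is solved per observation
via the smallest eigenvector of `AᵀA`, batched with one LAPACK call per
stream. The homogeneous column of `A` is rescaled by the rig baseline
before forming normal equations; without this balancing the mm-scale
translation entries dominate the O(1) rotation entries and the noiseless
round-trip error saturates near 1e-6 mm, with it the round trip is exact
to ~1e-10 mm. No iterative reprojection refinement is applied — DLT is the
minimal method matching what two-camera gesture rigs use — but a midpoint
triangulator is included as an independent cross-check and agrees with the
DLT route to micrometres on clean data. Ray pairs closer than 1e-6 rad to
parallel, or coincident camera centres, are treated as degenerate: the
batched API flags them missing, the scalar API raises.

The fused confidence of a triangulated point is the minimum of the two
views' confidences: a keypoint seen poorly by either camera cannot be
reconstructed reliably.

Rigid registration is the standard SVD (Kabsch) solution of
`min Σ‖R p + t − q‖²` with the reflection corrected by flipping the
smallest singular direction, so det(R) = +1 even for near-planar point
clouds. Inputs that are collinear (second singular value ≤ 1e-9) or have
fewer than three correspondences are rejected.

## Alignment conventions

* **Clap interval**: the clapperboard frames themselves are excluded;
  the analysable content is strictly between them. (The alternative
  inclusive convention changes counts by two frames; the exclusive one is
  fixed here and used consistently by the generator and the trimmer.)
  After trimming, a 5-s margin is dropped from each end — in the emulated
  study the experimenters were in frame around the claps.
* **Downsampling** of the 100 fps reference to the video frame count T
  selects source indices `round(i·(N−1)/(T−1))`: uniform, endpoint-
  preserving, no interpolation (an interpolated variant exists behind a
  flag). Nearest-index selection can leave a phase offset of up to half a
  reference frame (≤ 5 ms); at conversational gesture speeds this
  contributes only a few millimetres and is part of what the error tables
  measure.
* **Validity**: an entry is valid when the reference tracked the marker
  AND every evaluated method reports confidence at or above τ (default
  0.3; a confidence exactly at τ counts as valid). One joint mask per
  sequence is intersected across all methods and used both for transform
  estimation and for error scoring, so every method is scored on the
  identical support.
* **Scale**: stereo methods are metric and get s ≡ 1. Monocular streams
  are scale-ambiguous; s is estimated per participant as the tape-measured
  right elbow–shoulder length divided by the mean estimated length over
  frames where both keypoints are valid, pooled over the participant's
  sequences.
* **Transform pooling**: one rigid transform per (participant, method),
  fit to all valid frame×keypoint correspondences of all of that
  participant's sequences, each weighted equally.

## Error metrics and statistics

Errors are per-(frame, keypoint) Euclidean distances on valid entries,
folded into 10 groups: sided thumb/middle-finger/wrist/elbow groups, the
two shoulders pooled, and cheeks+chin pooled as "face". Cell means are
unweighted within (participant, method, group); the overall per-method
error is the mean over participants of each participant's pooled mean —
participants, not frames, are the statistical unit, matching the ANOVA.
Empty cells stay NaN, never zero.

The one-way repeated-measures ANOVA uses the classical within-subject
decomposition (SS_method, SS_subject, SS_error), F = MS_method/MS_error
with df1 = k−1, df2 = (n−1)(k−1), and partial η² =
SS_method/(SS_method+SS_error). No sphericity correction is applied by
default (the uncorrected dfs are the design quantities of interest);
Greenhouse–Geisser is available behind a flag. Post-hoc comparisons are
paired t-tests over all k(k−1)/2 method pairs with p-values multiplied by
the family size (capped at 1); 95% CIs of the mean paired differences use
the t distribution with n−1 df and are reported per pair, unadjusted and
labelled as such. A zero-variance nonzero difference yields t = ±∞, p = 0,
and is flagged by the infinite statistic. Report tables display p < .001
as "<.001" but store raw values.

Gesture space: left+right wrist positions (laterality and time discarded)
are voxelized with floor indexing on half-open cells anchored at the
aligned-frame origin — the anchoring and boundary conventions are
package decisions, fixed so indices are unambiguous. Dice is
2|A∩B|/(|A|+|B|), undefined (error) when both sets are empty. The default
sweep is 10–100 mm in 10 mm steps; the curve is computed on one
participant's pooled sequences (participant 1 by default), with the
method stream restricted to valid frames like every other analysis.

The low-confidence breakdown compares the two stereo routes: among
(frame, keypoint) events where either stream is missing or below τ, it
reports N and the percentage split into first-only / second-only / both,
per group, with NA percentages when N = 0.

## Synthetic study generator

No recordings are distributed, so the generator is a first-class module
that emulates the study's structure:

* **Design**: 10 participants × 8 sequences × 3 cameras (one frontal, two
  at ±30° on a 3 m arc), 60-s sequences at 30 fps against a 100 fps
  reference; 2-s clap padding; 5-s margins. Per-participant constant bone
  lengths, with the elbow–shoulder segment drawn U(260, 320) mm and
  doubling as the tape measurement.
* **Motion**: a static torso anchor; shoulders and face move near-rigidly
  with small harmonic sway (yaw ≤ ~4°, translation ≤ ~12 mm); each arm is
  a shoulder→elbow→wrist→fingertip chain whose spherical angles are sums
  of 2–5 random harmonics in 0.2–2 Hz, spanning a gesture box of several
  hundred mm in front of the torso. Everything is deterministic under
  (seed, participant, sequence), with named substreams so adding a camera
  or method never perturbs other draws.
* **Reference stream**: the truth upsampled to 100 fps by cubic splines,
  displaced by a *fixed* per-keypoint outward offset (default 10 mm).
  This models the anatomical marker-vs-keypoint mismatch as a systematic
  bias — markers sit on the skin over bone landmarks, detectors point
  inside the body — which rigid alignment cannot fully remove; it sets
  the error floor for the stereo methods. Marker track loss is a
  per-frame hazard that is persistent by default: once lost, a keypoint
  stays lost for the sequence (lost tracks are not relabelled).
* **2D detections**: exact projections plus Gaussian pixel noise (1 px),
  plus confidences of base 0.97 with sd 0.03, penalized by ~0.75 when the
  camera→keypoint sight line passes through a torso capsule (radius
  160 mm). Occlusion is geometric, not statistical, so low-confidence
  events correlate with pose, as in real HPE. Independent 0.2% dropout
  models detector failures; points behind a camera are missing.
* **Monocular streams**: the truth in the frontal camera's frame,
  multiplied by a hidden per-(participant, method) scale U(0.8, 1.25),
  plus depth-axis noise that is *smooth in time* (0.05–0.5 Hz harmonics)
  and split into a shared whole-body component and per-keypoint
  components (combined sd 150 mm), plus small lateral noise (8 mm).
  Monocular depth errors drift coherently rather than flickering; the
  150 mm default is a modeling choice exposed in the configuration, since
  only the qualitative depth weakness of monocular lifting is documented.
* **Four methods**: the evaluated set comprises two stereo routes —
  triangulation from the diagonal camera pair (primary) and from a
  frontal+diagonal pair — and two monocular streams with independent
  noise and scale realizations. This yields the 2-stereo-vs-2-monocular
  within-subject design (k = 4, so df1 = 3 and df2 = 27 with n = 10)
  while keeping exactly one 2D stream file per camera per sequence
  (240 files in the default export).

**What passing tests show — and don't.** The generator reproduces the
*structure* of the validation problem: confidence-gated missingness, a
systematic reference offset, scale-ambiguous depth-degraded monocular
input, persistent reference dropouts. Pipeline correctness, exact
geometry, statistical machinery and the qualitative ordering
(stereo ≪ monocular; Dice rising with voxel size) are all established on
it. Absolute error magnitudes are not transferable to real recordings:
real detector noise is heavy-tailed and appearance-dependent, real
marker offsets vary with soft tissue and body orientation, and real
monocular lifting errors depend on the training distribution. On the
synthetic defaults stereo errors sit near the 10 mm offset floor, several
times smaller than real-world reports (~50 mm); the gap is the
unmodelled appearance noise, not pipeline behaviour.

## Numerical and degenerate-input choices

* Missingness is always an explicit flag; coordinates at missing entries
  are NaN, never sentinels. Streams round-trip bit-exactly through the
  JSON/CSV formats (floats written as shortest round-trip decimals).
* Canonical keypoint order is right-before-left, proximal-to-distal, chin
  last, fixing CSV column order. The cheek proxies in the built-in
  estimator schemas (face-contour points 2/14 for the 133-layout,
  face-mesh points 205/425 for the 543-layout) are package conventions
  for "nearest facial point", not facts about any particular model;
  custom mappings can be supplied as JSON schema files.
* Empty error tables, two empty occupancy sets, ANOVAs with missing
  cells, scale estimation without a valid elbow–shoulder frame, and
  rank-deficient rigid fits all raise typed errors rather than returning
  silent defaults.
* Pipeline stages communicate only via files and write manifests with a
  configuration hash and per-file SHA-256 digests; reruns with the same
  seed are byte-identical.

## Problem sizes

The default study (80 sequences × ~1500 analysed frames × 13 keypoints
× 4 methods ≈ 5.5 M error records) is processed fully vectorized: a
complete analysis takes ~25 s and the full file export ~1 min on one CPU.
Unit and property tests run on 1–3 participant studies with 4–20 s
sequences, which exercise every code path at a fraction of the cost.

## Known limitations

* Two-camera triangulation only; no bundle adjustment, no >2-view fusion.
* No automatic clap detection; clap frames are metadata.
* Per-participant (not per-sequence) alignment transforms, matching the
  emulated protocol.
* The generator has no hand articulation beyond two fingertip points, no
  lower body, and renders no imagery — occlusion and confidence are
  modelled directly at the keypoint level.
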