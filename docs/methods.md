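# Methods

This note documents the models and procedures implemented in `backstep`, the
assumptions behind them, the defaults that matter, and what the synthetic
benchmarks do and do not demonstrate.

## Coordinate conventions

All kinematic analysis runs in a side-view, 2-D analysis frame with x
positive toward anterior and y positive toward dorsal (y-up). Pose tables in
the pose-estimation dialect store image coordinates (y grows downward); the
reader negates y on input and the writer negates it back, so files round-trip
bit-exactly (floats are serialized with `%.17g` and parsed with exact
rounding). With this orientation, the anterior extreme position (AEP) of a
tarsal-tip trajectory is simply its max-x point, the posterior extreme (PEP)
its min-x point, and the dorsal extreme (DEP) its max-y point — no per-call
orientation flags.

## Leg model and joint angles

Each leg is a planar four-segment chain (coxa, femur, tibia, tarsus) with
five landmarks from the body-coxa joint to the tarsal tip. Joint angles are
unsigned interior angles in degrees, clipped to [0, 180], matching how such
angles are usually plotted; the body-coxa angle is measured against the body
axis through two midline landmarks (anterior minus posterior), falling back
to the +x axis if those are absent. Whether the body axis should run through
the notum or the abdomen is not observable from our inputs; the two midline
landmarks are simply whatever the pose table provides under
`body_anterior`/`body_posterior`.

Frames in which any defining landmark has confidence below 0.9 are NaN and
excluded from all means (the corresponding manual quality-control step of a
human analysis). Coincident adjacent landmarks make the angle undefined for
that frame; the value is NaN and a warning is emitted.

`forward_kinematics` poses the chain with a fixed bend sense per joint,
alternating clockwise/counterclockwise, which reproduces the zigzag side-view
posture of an insect leg. Any consistent convention would satisfy the
distance and interior-angle contracts; this one is also exactly consistent
with the synthetic generator's inverse kinematics (below), which the tests
exploit as a round-trip oracle.

## Synthetic gait generator

The generator prescribes the tarsal-tip path of each leg: during stance the
tip moves at ground height (y = 0) along a straight segment from AEP to PEP
(PEP to AEP in backward mode); during swing it returns along a half-ellipse
peaking at `swing_height`. Only the extremes of the path enter the step
metrics, so the particular smooth arc is immaterial. The cycle phase of leg
`l` is `(f·t + offset_l) mod 1`, with stance occupying the first
`duty_factor` of the cycle. The tripod preset puts {LF, RM, LH} at phase 0
and {RF, LM, RH} at phase 0.5. Inter-leg phasing during backward walking is
left a free parameter rather than asserting a backward-gait preset, since the
coupling pattern under descending-neuron activation is not established.

Joint angles are obtained by closed-form two-link inverse kinematics: the
body-coxa angle is held fixed (default 120°), the tarsus is collinear with
the tibia, and the femur and the combined tibia+tarsus link solve the
two-link reach problem for every tip position. Landmarks, joint angles and
the tip path are therefore mutually exact: at zero landmark noise,
recomputing angles from landmarks reproduces the stored truth to
floating-point precision, and `forward_kinematics` of the stored angles
reproduces the landmarks. An earlier design sketch with prescribed sinusoidal
angle waveforms was dropped because it cannot make the tip path and the
angle truth simultaneously exact.

Default geometry (mm): segments (0.8, 1.6, 1.4, 0.8), body height 2.5,
anchors at x = +2/0/−2 for fore/mid/hind; AEP/PEP at ±1 relative to the
anchor, swing height 0.4, step frequency 2 Hz, duty factor 0.5. These give
step sizes, stroke amplitudes and cadences in the range typical of tethered
walking at 200 frames/s while keeping every tip position comfortably inside
the two-link workspace. Landmark noise is additive isotropic Gaussian.
Noise streams are spawned per leg (and one for the midline landmarks) from
the master seed, so adding legs never perturbs existing ones, and identical
seeds give bit-identical datasets.

What the generator does *not* emulate: perspective and occlusion effects of
real single-camera tracking, tracker-specific error structure (confidence is
constant 1), body translation/rotation on the ball, and inter-step
variability. Passing the recovery tests therefore demonstrates correctness
of the analysis chain, not robustness to every failure mode of real pose
estimation.

## Swing peaks, step windows, averaging

Swing peaks are local maxima of the z-scored tarsal-tip height with
prominence ≥ 1.0 z and minimum separation 50 ms (both config-exposed;
the original workflow used manual proofreading instead of fixed detection
parameters, so these defaults are our interpretation).

Step windows are swing-peak-aligned. Two presets ship:

* `short` — 100 frames (0.5 s at 200 fps) with the peak at index 49
  (49 frames before, 50 after);
* `long` — 300 frames (1.5 s) with the peak at index 40 (200 ms shown
  before the peak).

A step is truncated 8 frames (40 ms at 200 fps) clear of a neighbouring
swing peak that falls inside its window, at both ends; the same margin is
used for both presets for uniformity. Truncated tails are NaN, never
zero-filled, and are excluded from the averaging denominator. Steps clipped
to nothing by an analysis window are dropped and counted.

The swing interval of an averaged step is inferred from the averaged tip
height: the trace is smoothed with an 11-point local-quadratic
(Savitzky–Golay) filter, and the bout around the alignment peak is delimited
where the vertical velocity crosses 10% of its peak magnitude — scanning
backward from the peak through the rising flank for lift-off, forward
through the falling flank for touch-down. "Inflection point" admits several
operational readings; this velocity-threshold reading is robust on averaged
(hence smooth) traces and recovers the true interval with Jaccard ≥ 0.8 on
synthetic gait.

Scalar step metrics: step size |AEP − PEP|; swing-stroke amplitude =
distance from DEP to the closed segment AEP–PEP (verified against a dense
point-sampling oracle to 1e-6 mm); joint-angle range = max − min within a
step; step frequency = reciprocal of the mean inter-peak interval; maximal
post-stimulus flexion = minimum angle within 1 s of stimulus onset evaluated
up to the first re-extension (first local minimum followed by a rise
exceeding 5°, config-exposed); minimum stance angle = pre-peak minimum of a
step's angle trace; flexion slope = OLS slope from the averaged trace's
maximum to the window end, in degrees/s.

## Footfall patterns and co-swing

The co-swing index of a leg pair is (frames both in swing) / (frames either
in swing) over a half-open frame window; frames, not continuous time, are
the integration unit. The index is symmetric, bounded in [0, 1], and NaN
when neither leg swings in the window.

The automated swing/stance labeller ("height" method) z-scores each leg's
tip height and applies hysteresis: frames at or above 0.5 z seed a swing
bout, which extends down to just above the stance floor (5th percentile plus
5% of the range); bouts and gaps shorter than 3 frames are removed. A single
hard threshold at 0.5 z systematically clips the low-velocity shoulders of
each swing bout (~17% of frames for a half-elliptical swing at duty 0.5);
the hysteresis extension recovers them while the 0.5-z seed still rejects
stance-level noise. Provided annotation files are passed through unchanged,
with no despeckling. Pair classes (3 intrasegmental, 12 intersegmental
ipsi/contra per fly) are computed from the pair definitions; the grouping
column is exposed so alternative groupings can be aggregated.

## Calcium response mapping

Sessions are (T × Z × Y × X) volumes, by default 60 volumes at 1 volume/s
and 10 sessions per sample, concatenated in acquisition order into a
600-volume hyperstack. Motion correction is per-slice rigid integer
translation by phase correlation against the time-mean (or a chosen) volume;
sub-pixel and non-rigid correction are out of scope, and `mode="none"`
bypasses it.

ROI ΔF/F uses volumes 2–9 (one-based) of each session as baseline: F(t) is
the ROI-mean intensity, F0 the baseline mean, ΔF/F = (F − F0)/F0, averaged
across sessions. ΔF/F is invariant to any positive gain on the raw data.
Kernels are pointwise means of session-averaged ΔF/F traces from
strongly-responding ROIs (optional smoothing, off by default). The
synthetic-data module also provides a model kernel — the stimulus boxcar
convolved with a normalized difference of exponentials (rise 0.2 s, decay
1.0 s at the volume rate, peak 1) — which stands in when no measured ROI
traces exist.

Per-voxel response vectors are unnormalized lagged cross-covariances
between the demeaned voxel series and the demeaned kernel tiled across
sessions, at lags −5…+5 volumes (11 values; zero padding outside the
overlap). Positive lag means the voxel lags the kernel. Tiling is the only
length-consistent way to correlate a session-length kernel against the full
hyperstack given that the stimulus repeats identically each session; an
equivalent alternative (correlate per session and sum) would give the same
result up to session-boundary edge terms. A "biased" 1/N normalization is
config-exposed and changes only scale, never map topology. The activated
map is the per-voxel maximum positive value (0 if all 11 are negative); the
inhibited map the minimum negative value (0 if all are positive).

Detection thresholding (used by the recovery benchmarks, not by the map
construction itself) marks voxels whose |map| value exceeds the background
by 5 robust SDs (median + 5 × 1.4826 × MAD). The 5-SD level is a
multiple-comparisons choice: across the ~10⁴–10⁵ voxels of a volume a 3-SD
cut already admits a few dozen false voxels from the max-over-lags statistic
alone, while true responses at the pipeline's working signal-to-noise
(peak response ≥ 5× noise SD) sit tens of SDs above background. The level
was fixed once against pilot simulations and is config-exposed.

The synthetic scenes embed disjoint box-shaped cells with signed amplitudes
and integer lags on a constant background with i.i.d. Gaussian noise
(per-session streams). They do not emulate photobleaching, slow drift,
correlated (shot/motion) noise, or overlapping neurites; recovery results
bound the method's behaviour under its own model assumptions only.

## Arena locomotion

Heading-projected speed assigns each frame-to-frame displacement the heading
of the earlier frame (matching per-frame tracker output semantics) and
projects it onto (cos θ, sin θ); positive is forward. Backward distance
accumulates |v|·Δt over stimulus episodes for frames with v ≤ −1.5 mm/s
(threshold config-exposed; monotone non-increasing in the threshold).
Forward distance is the net signed integral over the first 45 s with no
threshold. Arena position is ignored throughout; identity swaps and track
breaks are assumed resolved upstream. The standard schedule is nine 5-s
episodes, one per minute starting at 60 s.

The arena simulator moves responder flies anti-parallel to their heading at
5 mm/s during episodes and forward at 10 mm/s otherwise — round numbers in
the range of adult fly walking speeds — with a seeded random-walk heading.
Because the simulator uses the same earlier-frame heading convention as the
analysis, distances are recovered to numerical precision; on real tracker
output the convention mismatch would contribute at most one frame's
displacement per transition.

## Problem sizes

The test suite and the acceptance script run the gait pipeline on 10-s
six-leg bouts at 200 fps, calcium recovery on 8 × 32 × 64-voxel scenes with
10 sessions of 60 volumes, and arena cohorts of ~10 flies over 10-min
protocols — sizes at which every ground-truth comparison is exact or
tightly bounded while the full suite completes in well under a minute.

## Known limitations

* Kinematics is strictly 2-D side-view; out-of-plane leg motion biases
  angles on real data and is not modelled.
* The swing-interval inference assumes a single swing bout per averaged
  window (true for peak-aligned averages of periodic stepping).
* Motion correction is integer-pixel rigid translation per slice.
* The co-swing analysis does not classify gaits or fit phase oscillators.
* Statistical hypothesis testing is intentionally excluded; the package
  emits per-fly/per-step tidy tables for external tools.
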