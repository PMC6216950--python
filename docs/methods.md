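# Methods

## Scope and coordinate conventions

The package measures routine swimming speed from still-photo sequences
and maximum swimming speed (U_max) from incremental swim-chamber
trials, for larval fish photographed as dark, semi-transparent bodies
against a uniformly backlit background. Images use the top-left-origin
convention: `x` = column, `y` = row, rows increase downward, so
physical "up" is the negative row direction. All physical speeds are in
cm/s; the pixel scale `cm_per_px` comes from a reference object of
known size (e.g. a 1 cm grid photographed in the tank), entered either
directly or as two pixel points spanning a known distance. Grid
auto-detection is deliberately not attempted; scale entry is an
explicit, logged user step. Frame indexing is 0-based; with a nominal
frame rate, frame *k* is stamped *k*/fps seconds.

## Detection

Per frame: threshold → connected components (8-connectivity) → area
filter → fragment merging → mass centroid.

**Thresholding.** The default `background` mode estimates the backlit
background level by the frame median and its spread by the MAD, and
takes as foreground every pixel darker than
`median − max(k·MAD, contrast_floor)` (defaults k = 6,
floor = 0.08 full scale). This exploits the structure of tank
photographs — larvae occupy a vanishing fraction of pixels (tens of
bodies of ~30 px in a megapixel frame), so the median is a clean
background estimate. The classic Otsu split is provided as `otsu` (with
a degenerate-histogram guard returning an empty mask on blank scenes)
but it is *not* the default: when the dark class is very sparse, Otsu's
between-class criterion places the threshold inside the background
noise and floods the mask — on a representative synthetic scene it
marked ~45 % of pixels foreground. A user-supplied `fixed` level is the
third mode. Optional: a rectangular ROI (everything outside is
background) and a morphological opening (off by default; the area
filter is the only default noise-reduction step).

**Merging.** Translucent larvae can fragment into several components.
Components surviving the area filter whose centroids lie within
`merge_distance_px` are unioned by single-linkage, applied transitively;
the merged detection's centroid is the unweighted mean of all member
foreground pixels (binary mass centroid), and the number of merged
components is retained for QC. Single linkage is chosen because
fragments of one fish form a chain along the body; the recommended
merge distance is one expected body length in pixels (fragments of one
fish are at most a body length apart; distinct fish are normally
farther). Detection counts are monotone non-increasing in both the area
threshold and the merge distance.

## Tracking

Detections are linked frame-to-frame under a displacement gate
`gate_px`, defaulting to (max plausible speed × Δt)/cm_per_px with a
max plausible speed of 31 cm/s — just above the largest routine speed
observed in larval carps (30.72 cm/s), so gating never excludes real
behaviour. Two linkers:

* **greedy** (default): candidate (track, detection) pairs within the
  gate are taken nearest-first; ties break to the lower track id, then
  the lower detection index. This mirrors the simple centroid-comparison
  tracking of the original bench software.
* **optimal**: per frame pair, the minimum-total-distance bipartite
  assignment (Hungarian algorithm) under the same gate. It exists
  primarily as an independent oracle: on scenes whose larvae stay far
  apart relative to the gate the two linkers provably coincide, and the
  tests assert exact agreement on 50 such scenes.

Unmatched detections open new tracks at any frame (larvae swim into the
photographed window, which excludes tank walls); a track unmatched for
more than `max_missed_frames` consecutive frames terminates. The
default is 0 (no gap closing): low-frame-rate sequences were repaired
by human inspection in the original workflow, not by algorithmic gap
closing. Linking conserves detections exactly — every input detection
appears in exactly one track.

**Known limitation — identity switches.** Both linkers are memoryless
(no motion model; Kalman-style prediction and appearance models are out
of scope), so when two paths cross within the gate the identities can
swap. Such events are surfaced by the QC report (frames where the
detection count changes, steps exceeding a speed cap, very short
tracks) and are repaired through the manual-correction surface: a JSON
edit list of split / join / delete / reassign actions, validated
against the track invariants (one detection per frame, strictly
increasing frames) and marked `status="corrected"`. Validation of speed
recovery on synthetic truth therefore scores each larva on its
position-matched track segment (consecutive detections within 5 px of
the true centroid), which measures speed fidelity without conflating it
with identity maintenance.

## Kinematics

One movement = one consecutive detection pair of one track: pixel
displacement × cm_per_px over the timestamp difference. The row
displacement is negated so upward is positive. Zero-length steps are
retained (a motionless larva is a real observation; routine-speed
minima are near zero). Direction accounting is by vector components:
each movement contributes |vertical component| to the upward *or*
downward group according to its sign, its |horizontal component| to the
horizontal group (left and right pooled; purely vertical steps
contribute nothing horizontal), and its vector magnitude to the
overall group. No dominant-axis classifier is applied. Summaries report
mean, sample SD (n−1; NaN for a single movement), min, max and the
movement count n; empty groups are omitted, never zero-filled. The
square-root transform is available for plotting daily speeds on a
compressed scale and is never used in statistics.

Under vertical mirroring of all frames the upward and downward groups
exchange exactly in exact arithmetic; in floating point the mirrored
centroid quotient `((H−1)·n − S)/n` can differ from `(H−1) − S/n` by
~1e−14 relative, so the symmetry test asserts counts exactly and speed
statistics at 1e−12 relative tolerance.

## Swim chamber

Water velocity in the chamber follows the pump line
`U = 0.0218·Hz − 0.0731` cm/s. The line is negative below its zero
crossing (~3.353 Hz); such values are returned as-is with a
non-physical flag, never clamped. The step protocol raises velocity by
`U_i` (default 0.218 cm/s) every `t_i` (default 2 s) from a start speed
kept below the slowest fish of the previous day. The nominal "~0.1 Hz"
description of the increment is inconsistent with the line's slope
(0.1 Hz ≈ 0.00218 cm/s); the implementation takes U_i = 0.218 cm/s as
authoritative since that value also defines the penultimate speed in
the U_max formula.

`U_max = (U_final − U_i) + (t/t_i)·U_i`. The bench convention records
t = 0 (failure is scored at the moment the increment starts being
unsustainable), collapsing the estimate to the penultimate speed; the
general formula is kept with `t_final` configurable so partial-increment
credit is available. By construction the estimate lies within one
increment of the true maximum — the deterministic trial simulator plus
this formula give `0 ≤ U_true − U_max ≤ U_i` always, which the tests
bound over 200 random trials. A logistic-stochastic failure mode
(failure probability per increment logistic in speed − true U_max,
uniform failure time) is available for less idealised cohorts.

Relative speed `U_maxrel = U_max / TL` (total lengths per second) uses
the *daily mean* total length by default, because lengths are measured
post-mortem on a daily sample and cannot generally be paired with
individual swum fish; a per-fish option exists and is labelled as the
non-standard variant. Daily means report mean ± sample SD of U_max,
TL, stage and relative speed per species × day.

## Ontogeny regressions

Simple OLS of daily mean U_max on days post-hatch, daily mean total
length (mm) and daily mean developmental stage (ordinal stages 31–48,
squamation = 48), per species — statsmodels supplies the fit and the
two-sided slope t-test (n−2 df); R² = 1 − SSres/SStot. Regressions run
on daily means, not per-fish records, matching how the lengths and
stages are sampled; requirements are n ≥ 3 and non-constant x. No
multiple-testing adjustment is applied across the nine cells. Tests
cross-check the fit against closed-form identities (R² = squared
Pearson r, slope scale-equivariance) and a brute-force SSE grid.

## Synthetic data

**Scenes.** Larvae are filled anti-aliased ellipses (default 12 × 3 px,
opacity 0.7) oriented along their direction of travel,
alpha-composited (`pixel ×= 1 − opacity·coverage`) onto a uniform
background (default 0.85) with optional additive Gaussian sensor noise;
coverage is estimated on a 3×3 subpixel grid. Trajectory kinds:
constant velocity, isotropic Gaussian random walk, and vertical drift
with lateral jitter. Truth records per larva and frame the exact
ellipse centre and the finite-difference world velocity (exactly the
programmed velocity for constant-velocity larvae). Rendering is
bit-deterministic given the spec and seed. Frame timestamps are k/fps
with an optional jitter parameter emulating variable-interval capture
(2–3 fps cameras). Frame rates of 2–7 fps and speeds of 0–30 cm/s span
the conditions reported for larval carps.

Two cohort builders define the standard validation conditions: a
speed-survey scene (default 20 larvae, 60 frames at 6 fps, speeds
uniform in 0.5–5 cm/s, noise σ = 0.02, 1100 × 900 px at 0.05 cm/px —
sized so most larvae remain in view for tens of frames) and a
pre-gas-bladder vertical cohort whose alternate members swim straight
up at a base speed and straight down at ratio × base (default ratio 2,
emulating the sink-and-swim pattern in which downward travel is up to
twice as fast as upward before the gas bladder inflates).

What the renderer does **not** emulate: body flexion and tail-beat
articulation, lighting gradients and vignetting, refraction and
shadows, the physical calibration grid, occlusion by tank furniture,
and depth (out-of-plane) motion. Passing the pipeline tests therefore
shows the measurement chain is correct for well-contrasted rigid
bodies with known scale — not that segmentation parameters transfer to
any particular camera setup, which must be tuned per cohort.

**Chamber cohorts.** The campaign generator uses per-species affine
ontogeny lines for U_max against age as ground truth, with the length
and stage trajectories *derived by inverting* the corresponding
length and stage lines at the day's mean U_max, so one simulated
cohort is internally consistent across all three predictors.
Measurement days run daily from 4 DPH (first horizontal swimming) for
two weeks, then weekly until the stage trajectory reaches squamation
(stage 48), with 10–20 fish per day; each fish's true maximum is the
day mean with 15 % coefficient of variation, lengths vary 4 % about the
day mean, stages 0.4 about the day trajectory (clipped to 31–48), and
every fish is run through the deterministic step protocol so recorded
speeds carry the protocol's quantization. Fish whose true maximum falls
below the day's start speed are flagged and excluded, as at the bench.

## Validation problem sizes

The standard suite uses: one 20-larva 60-frame survey scene for
pipeline recovery (≥95 % of larvae within 10 %), 50 five-frame scenes
for greedy/optimal agreement, one 12-larva 40-frame vertical cohort for
the mirror-symmetry and 2:1 asymmetry checks, 200 chamber trials for
the quantization bound, and one full three-species campaign
(~750 trials) for regression recovery. `scripts/acceptance.py` re-runs
exactly these computations from a fresh seed and writes the measured
quantities as JSON.
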