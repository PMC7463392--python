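# Methods

## Problem and approach

A physiotherapy exercise performed at home lacks the qualitative feedback a
physiotherapist would give in the clinic.  `exerscore` quantifies how
closely a recorded performance matches a reference performance (typically a
physiotherapist's) by two complementary similarity scores on joint-angle
trajectories:

* **S_D** — a distance-based score from multivariate dynamic time warping
  (DTW), sensitive to detail;
* **S_H** — a likelihood-based score from a discrete hidden Markov model
  (HMM) trained on the reference, capturing the coarse structure of the
  motion.

Both are percentages anchored at two extremes: the reference itself (≈100%)
and an explicit *worst performance* — not moving at all, i.e. holding the
rest pose for the whole repetition.

## Features

Raw 3D joint positions depend on body size and placement relative to the
camera, so each exercise is described by invariant scalar angles per frame:
interior angles at a joint (e.g. the knee angle between thigh and shank)
and segment inclinations against the body vertical (e.g. arm elevation).
A performance is the matrix T (frames × features, degrees): 3 features for
the lunge, 2 for shoulder abduction, hip abduction, and sit-to-stand.

The concrete joint triplets per exercise (see `features.builtin_spec`) are
package choices guided by the clinical descriptions of correct execution —
for shoulder abduction, arm elevation is the range-of-motion feature and
the elbow angle indicates whether the arm stays stretched; for hip
abduction the leg elevation dominates and the torso inclination is minor.
All definitions are overridable through `ExerciseSpec` without code
changes; scores are invariant to translation, uniform scale, and rotation
about the vertical (property-tested).

## Repetition handling

The recording protocol asks for at least five repetitions over ~20 s with
short pauses.  Repetitions are found on the dominant feature by
prominence-based peak detection (default prominence 20°) after a centered
5-frame moving average, with boundaries at the crossings of the rest band
(rest angle ± 10°); dip-shaped excursions are handled by operating on the
signed deviation's dominant polarity.  The first and last detected
repetitions are dropped before scoring (startup/wind-down artifacts), so a
5-repetition session contributes its middle 3.  Automatic segmentation can
be bypassed with explicit frame boundaries — necessary both for
degraded performances whose excursions fall under any detection threshold
and for the worst-performance baseline, which by construction contains no
excursions at all.  When the pipeline encounters an unsegmentable
participant without explicit boundaries, it scores equal-length slices of
the trajectory (with a warning) so that "did not move" yields a score near
0 rather than an error.

## DTW score

`dtw_distance` is the classic dynamic program with steps
{(1,0),(0,1),(1,1)}, unit step weights, no window, and local cost equal to
the Euclidean distance between feature rows (all features jointly).  It is
oracle-tested against exhaustive path enumeration.

The worst trajectory T_W is the constant rest-pose matrix.  The upper bound
is D_u = mean over reference repetitions r of DTW(r, T_W(len(r)))
(aggregation configurable: mean or max).  A distance D maps to

    S_D = 100 × (1 − D / D_u)

so D = 0 gives 100% and D = D_u gives 0%.  The participant score averages
the 3 × 3 = 9 pairwise repetition comparisons.  Per-pair values are kept
unclamped (a value below 0 means "farther from the reference than not
moving"); the final average is clamped to [0, 100].  Clamping the average
rather than each pair keeps the worst-performance anchor exact: a
constant-rest participant's mean pairwise distance equals D_u by
construction, so S_D is exactly 0 instead of being biased upward by
per-pair truncation.

## HMM score

Features are vector-quantized to product symbols (nearest center per
feature, ties to the lower center, row-major combination).  A single
discrete HMM (default N = 5 states, ergodic) is trained on the quantized
reference repetitions by Baum-Welch (hmmlearn's `CategoricalHMM` under the
hood) with uniform initial distribution and seeded near-uniform A and B;
EM is restarted 3 times from distinct seeded initializations and the best
final likelihood is kept, the usual guard against local optima.
Convergence: tolerance 1e-4 on the total log-likelihood, at most 200
iterations; the per-iteration history is retained and is non-decreasing
(EM guarantee, tested).  After training, emission rows are floored at
1e-6 and renormalized so unseen symbols stay finitely unlikely.

A performance is scored by its length-normalized forward log-likelihood
L = log P(symbols | model) / length (own log-space implementation,
oracle-tested against the exhaustive path sum and against hmmlearn).  With
L_u = 0 and L_l the likelihood of the quantized worst trajectory,

    S_H = 100 × (L − L_l) / (0 − L_l)

averaged over the 3 repetitions, clamped like S_D.

### Why quantization must isolate the rest pose

A constant symbol sequence pays no state-transition costs, while any
varying sequence pays roughly the entropy of its run lengths (≈ −0.3 per
frame for realistic repetitions under their own best-fit model).  If the
rest pose shares a wide cluster with the motion onset, the "worst"
sequence is therefore *more* likely than the reference's own repetitions,
L_l collapses toward 0, and every score clamps to 0.  The default
quantizer (`hmm.default_quantizer`) consequently gives each feature a
narrow dedicated cluster at its rest angle — flanked by transition centers
±16° so that repetition-edge samples inside the segmentation rest band do
not land in it — plus a coarse 45°-spaced grid over [0, 180°].  The
reference then essentially never emits the rest symbol, the emission floor
makes L_l strongly negative, and the score separates moving from
not-moving as intended.  Center lists remain fully configurable (the
scoring API and CLI accept arbitrary per-feature centers).

Angles are smoothed with the same centered 5-frame moving average before
quantization: frame-to-frame sensor jitter on an angle that sits near a
cluster boundary otherwise makes the symbol flicker, which a discrete HMM
punishes severely (disable with `smooth_window=1`).

### Quantization sensitivity

Even so, S_H remains sensitive to where cluster boundaries fall relative
to the motion: regrouping identical data under a different grid can lower
the score for one grid but not its neighbors
(`examples/quantization_sensitivity.py` demonstrates this with 3-, 4-, and
5-cluster grids on identical data).  This is a property of the method, not
a defect of the implementation, and it is why the ROM-degradation study
protocol (below) uses an exercise whose peak angles sit mid-cluster at
every scale tested.

## Sensitivity factor

Both normalizers can be scaled (`ScoreBounds.scaled`, CLI
`--sensitivity`): multiplying D_u and |L_l| by 2 raises scores and shrinks
differences between participants (encouraging, early-stage feedback);
dividing by 2 lowers and sharpens them (late-stage discrimination).  The
effect is exact for S_D (spread scales by 1/factor until clamping) and
holds empirically for S_H.

## Synthetic data

The generator (`simulate`) emulates the recording protocol rather than any
particular subject: each feature follows rest + a raised-cosine pulse per
repetition (smooth, zero-derivative endpoints, matching the rounded peaks
of real recordings), with rest plateaus between pulses and additive white
Gaussian angle noise (default SD 1.5°, approximating depth-camera jitter).
Defaults: 5 repetitions × 2 s, 1.5 s pauses, 30 fps (≈ 19 s per session);
main-feature amplitudes of 80° for shoulder and hip abduction (the full
range of motion a healthy reference reaches), 85° knee flexion for the
lunge, and 90° hip/knee opening for sit-to-stand.  `rom_scale` and
`speed_scale` multiply amplitude and tempo to build graded cohorts;
`prescribed_boundaries` exposes the generator's own pulse windows so
degraded cohorts can be scored without relying on automatic detection.

`simulate_skeleton_session` additionally places a 25-joint stick figure so
that feature extraction reproduces the prescribed curves exactly (interior
angles are constructed by rotating about an axis orthogonal to the
reference limb, so the round trip is exact to machine precision; the test
budget allows 0.5°).  Limb lengths are fixed constants — scores are
invariant to them by design.

What the generator does *not* model: per-joint (rather than per-angle)
sensor noise, tracking dropouts and occlusions, biomechanical coupling
between features, within-session fatigue, or idiosyncratic movement styles.
Passing tests therefore show that the pipeline is correct and behaves as
documented under protocol-shaped data, not that scores are clinically
validated on real patients.

## Study protocols in `experiments`

* **ROM cohort** (`rom_cohort_scores`): participants at rom_scale 1.0 to
  0.2 against a full-ROM reference, 3 replicate noise realizations per
  scale, scored on shoulder abduction (peak angles mid-cluster at all
  scales, see above).  Mean S_D decreases strictly; mean S_H is
  non-increasing.
* **Sensitivity scaling** (`sensitivity_scaling_table`): the same cohort
  under bound factors 0.5 / 1 / 2.
* **Feature removal** (`feature_removal_contrast`): scores with and
  without the minor feature; dropping it raises S_D noticeably (less
  accumulated distance) while S_H, driven mainly by the main feature's
  cluster sequence, moves little — though retraining on the reduced
  codebook adds a few points of variability either way.
* **Quantization cases** (`quantization_case_table`): S_H for identical
  data under 3/4/5-cluster grids.

## Numerical choices and degenerate inputs

* Angles are degrees throughout; trajectory values are validated to
  [0, 360) and the simulator clips to [0, 180], the range of interior and
  inclination angles.
* Coincident joints (zero-length limb vectors) raise errors rather than
  returning 0°, to surface corrupt data.
* D_u = 0 (reference indistinguishable from rest) and L_l ≥ 0 are rejected
  as degenerate bounds.
* Quantization ties break toward the lower center; peak-plateau ties in
  segmentation take the first index.
* Session timestamps are normalized to start at 0 on read; round-trip I/O
  is exact to 1e-9.

## Known limitations

* Scores compare one performance against one reference; they do not
  localize *which part* of the movement was wrong.
* The HMM score depends on the quantization grid (see above) and on the
  training initialization (mitigated, not eliminated, by restarts).
* A performance can score 0 on S_D while still containing movement
  ("worse than not moving" relative to the bound); the per-pair values in
  the report expose this.
* Left/right comparisons assume mirrored joint sets are equally tracked by
  the sensor.
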