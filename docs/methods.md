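# Methods

This note records the models, conventions and design decisions behind
`penaltypose`, in the spirit of a statistical software methods appendix.

## Geometric model

The pitch is treated as a plane, so a fixed broadcast camera induces a
projective homography `H` between image pixels and metric pitch
coordinates. `H` is estimated once per penalty clip by the normalized
direct linear transformation: image and field points are each mapped by a
similarity transform to zero centroid and mean distance √2 (Hartley
normalization, always on — pixel-scale coordinates are badly conditioned
without it), the 2n×9 constraint system is solved by SVD, and the
normalizations are undone. With exactly four correspondences the solution
interpolates them to machine precision; with more it is the algebraic
least-squares solution. The matrix is stored normalized to `h₃₃ = 1`
(unit Frobenius norm in the rare `h₃₃ ≈ 0` case). Degeneracy (three
collinear points among a minimal four) is detected from the second-smallest
singular value and rejected. Lens distortion and camera intrinsics are out
of scope: corner annotations are taken as given, including corners whose
projections fall outside the image.

Field frame: origin at the centre of the attacked goal line, +x from the
penalty spot toward the goal, +y to the kicker's left. Nothing in the
mathematics depends on this choice; it makes 0° mean "facing the goal" and
aligns the right/left orientation buckets with the kicker's halves of the
goal. Default pitch dimensions are 105 × 68 m, overridable wherever used.

## Pose-derived measures

A landmark is *missing* when it carries the `(0, 0, 0)` sentinel or its
confidence is below the acceptance floor (default 0.05). The floor exists
because pose estimators emit near-zero-confidence garbage coordinates that
the sentinel alone does not catch; 0.05 is low enough never to reject a
genuinely seen landmark. Missing landmarks never enter geometry: each
measure either resolves a neighbouring frame (search order 0, −1, +1, −2,
+2, … up to a ±5-frame window; ties to the earlier frame, which is when
the kicking pose is least occluded) or degrades to an explicit missing
flag.

Orientation of an LR pair is the direction of the field-projected
`(right − left)` segment rotated +90° counter-clockwise, i.e. the outward
normal of the segment, measured counter-clockwise from +x in [0°, 360°).
The support foot is contralateral to the kicking foot, and its pair is the
hallux and fifth toe with the hallux treated as the medial point: on a
left support foot the big toe is the subject's right-side element, on a
right support foot the left-side element. Bucket boundaries are half-open
(90° → left, 270° → right) so the side Boolean is deterministic.

The goalkeeper anticipation angle is taken between *directed* neck→mid-hip
vectors at run-up start and ball contact, giving a range of [0°, 180°]: a
keeper who reverses lean direction scores near 180°, which an undirected
line interpretation (range [0°, 90°]) would fold back to small values.
The angle is computed after projection to field coordinates, removing
perspective distortion from the comparison of the two moments. Foot
displacements are plain Euclidean distances between the projected ankle
positions of the two moments. Ball speed is an external numeric input; a
displacement/time helper (`distance · fps / frame_gap`) is provided for
convenience.

Kicker/goalkeeper roles are assigned from the field-projected mid-hip at
ball contact: nearest the goal line → goalkeeper, farthest → kicker, with
equidistant ties going to the lower person index. Actor tracks are linked
across frames greedily by nearest mid-hip, falling back to stable person
ordering — adequate for two-actor scenes without camera cuts, which is the
only setting supported.

## OSPAF layer

The 21 coding variables and their level sets are fixed in
`ospaf_coding.OSPAF_LEVELS`, with canonical snake_case tokens and a synonym
map for the verbose phrases used on coding sheets ("Running with pauses" →
`with_pauses`). Validation is total: arbitrary input yields a violation
list, never an exception. The analysis table is an inner join of
notational, pose and ball-speed records on `penalty_id` (outer-with-NaN
available by configuration). The "unclear" strategy level is retained in
the data model but excluded from all dichotomous analyses.

## Statistical layer

Chi-squared tests are Pearson's without continuity correction, and no
multiple-testing adjustment is applied at screening — raw p-values against
α = 0.05 — because the workflow this package implements reports raw
per-variable associations. Cramér's V uses
√(χ²/(N·(min(r,c)−1))), banded weak ≤ 0.2 < moderate ≤ 0.6 < strong.
Test-retest bands: 1 perfect; ≥ 0.9 excellent; ≥ 0.8 good; ≥ 0.7
acceptable; ≥ 0.6 questionable; ≥ 0.5 poor; < 0.5 unacceptable; exactly 0
none. Both band functions are exact step functions, tested at their
boundaries.

Confidence summaries (mean ± sample SD, n−1 denominator) are rounded to
two decimals in decimal arithmetic (half away from zero) on the decimal
string form of the inputs, so that summaries of two-decimal scores come
out as a desk calculator gives them; binary floating-point rounding would
report 0.795 as 0.79.

The logistic models use the enter method: all candidate predictors
simultaneously, no stepwise selection. Categorical predictors are
dummy-coded with the first alphabetical canonical token as reference (the
coding is otherwise arbitrary; alphabetical is deterministic). The model
statistic is the likelihood-ratio χ² = 2(LL_full − LL_null) with degrees
of freedom equal to the number of predictor terms. Classification
accuracy is in-sample at threshold 0.5, with p̂ = 0.5 ties predicting the
positive (dependent-strategy) class. Fitting is Newton ML via
statsmodels; complete separation — common at n ≈ 34 with a strongly
separating pose variable — is detected and reported with a warning, the
coefficients then coming from a capped-iteration BFGS fit (their
magnitudes are not interpretable; the accuracy and LR statistic are).
Numeric predictors may carry NaN missing flags; model rows are restricted
to complete cases on the entered predictors.

## Synthetic generators

`simulate_scene` constructs both skeletons analytically in field
coordinates — the measured pairs placed so that the planted orientation
angles, anticipation angle and foot displacements hold exactly — and
pushes every landmark through a field→image camera homography (default: a
behind-the-kicker view with ≈ 50 px/m across the goal, ≈ 30 px/m in depth,
mild perspective). Noise is isotropic Gaussian in pixels, independent per
landmark; confidences are clipped Gaussian draws (default 0.80 ± 0.14,
floor 0.05) that are decorative except for exercising the acceptance-floor
path. Scenes run 50 frames at 25 fps with the analysed moments at frames
5 and 44 (a two-second run-up). What the generator deliberately does not
model: occlusion, blur, pose-estimator error correlation across landmarks
and frames, camera shake, or heavy-tailed failure modes. Passing recovery
tests therefore demonstrates the correctness of the geometry and plumbing,
not robustness to real broadcast-footage pathologies.

`simulate_ospaf_dataset` draws the binary strategy at a configurable
prevalence (default 0.5), each categorical from strategy-conditional level
probabilities, and numerics as strategy-conditional Gaussians. The default
study conditions plant the association pattern the method is meant to
detect: for the goalkeeper outcome, tactical action at population φ = 0.8,
run-up speed at φ = 0.35, and an anticipation angle separated by d ≈ 6.75
standard deviations (18° vs 72°, SD 8° — the separation implied by a
point-biserial correlation near 0.96), all other variables independent;
for the taker outcome, run-up speed/fluency/gaze/deception at φ = 0.24 /
0.38 / 0.76 / 0.47 with ball speed the separating numeric. The population
φ implied by each binary variable's conditionals is returned with the
sample and serves as the oracle in association-recovery tests.

## Problem sizes and numerical choices

Default simulated studies use n = 34 penalties (the sample size of the
workflow's natural use case); recovery and calibration checks use 200
noise replicates, n = 2000 for association recovery, and 20 replicates of
n = 200 for the null screening rate — sizes at which the Monte-Carlo error
of each checked quantity is several times smaller than its tolerance.
Homographies reject configurations with near-zero second-smallest singular
values; projections reject homogeneous weights below 1e−12 (point at
infinity); LR pairs closer than 1e−6 m are degenerate. All simulation
randomness flows from a single integer seed through
`numpy.random.default_rng`; equal configurations give byte-identical
outputs.

## Known limitations

Single camera, single homography per clip, planar assumption: player
landmarks above the ground plane (shoulders, neck) are projected onto the
pitch, so absolute projected positions carry a height-dependent offset;
the orientation and anticipation measures compare directions, which this
offset largely cancels, but it is not modelled. Two-actor scenes only; no
re-identification across cuts. The logistic accuracies are in-sample, as
in the workflow being implemented — with ~30 effective cases and several
dummy terms they are optimistic, and complete separation is expected
rather than exceptional. Inter-observer agreement of the coding scheme
(kappa) is an input from the instrument's validation, not computed here.
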