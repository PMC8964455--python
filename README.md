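# penaltypose

Penalty-kick strategy analysis from 2D pose keypoints, planar field
registration and notational (OSPAF) coding.

## The problem

In elite football, a penalty taker either pre-commits to a target
(keeper-independent strategy) or adapts the shot to the goalkeeper's
movement during the run-up (keeper-dependent); symmetrically, the
goalkeeper either reacts to the taker (kicker-dependent) or gambles on a
corner (kicker-independent). Observational coding schemes can classify
these strategies from broadcast video, but purely notational variables miss
the continuous kinematics of the duel. `penaltypose` combines both
sources: it derives body-orientation and anticipation metrics from
markerless 2D pose keypoints (the BODY_25 skeleton dialect: 25 landmarks,
each `(x, y, confidence)`), registers them onto the pitch plane, merges
them with the 21-variable OSPAF coding of each penalty, and runs the
strategy-association analysis.

It is aimed at performance analysts and movement scientists who already
have pose-estimator output and coded penalty events, and at methodologists
who want a fully synthetic, ground-truth-controlled test bed for this kind
of pipeline.

## What it computes

**Field registration.** The image-to-pitch map is a 3×3 homography
estimated by the normalized direct linear transformation (DLT) from ≥ 4
point correspondences (typically the pitch corners, which may project
outside the visible frame):

```
[x′, y′, 1]ᵀ ∼ H [x, y, w]ᵀ
```

The field frame puts the origin at the centre of the attacked goal line,
+x from the penalty spot toward the goal, +y to the kicker's left.

**Body orientation.** For an anatomical left–right landmark pair
(shoulders 2/5, hips 9/12, or the hallux/fifth-toe pair of the support
foot), the facing vector is the field-projected `(right − left)` segment
rotated +90° counter-clockwise; the orientation angle α is measured
counter-clockwise from +x (0° = facing the goal). The side Boolean is
*right* on [0°, 90°) ∪ [270°, 360°) and *left* on [90°, 270°). Each
measure carries the mean confidence of its pair (C_Sh, C_Hi, C_SF).

**Goalkeeper anticipation.** α_GK ∈ [0°, 180°] is the angle between the
directed neck→mid-hip body-axis vectors at the two analysed moments —
run-up start and ball contact — computed after projection to the pitch
plane; D_GKL and D_GKR are the metric displacements of the projected
ankles between the moments, and C_GK averages the neck and mid-hip
confidences of both frames.

**Statistics.** Categorical OSPAF variables are screened against the
dichotomized strategy with Pearson χ² (no continuity correction) and
Cramér's V = √(χ²/(N·(min(r,c)−1))), banded weak (V ≤ 0.2) / moderate
(0.2 < V ≤ 0.6) / strong (V > 0.6); numeric variables with the
point-biserial correlation; repeated measurement runs with test-retest
Pearson r banded from perfect (r = 1) to unacceptable (r < 0.5). Variables
with p < α (default 0.05) enter an enter-method logistic regression, first
notational-only, then with the pose variables added, each reported with the
likelihood-ratio model χ² = 2(LL_full − LL_null) and in-sample
classification accuracy at the 0.5 threshold.

**Synthetic scenes.** `synthetic_scenes` builds kicker/goalkeeper skeleton
tracks analytically in field coordinates (so the planted angles and
displacements are exact by construction), pushes them through a
behind-the-kicker camera homography, adds Gaussian pixel noise and
confidence draws, and writes the same file dialects the real pipeline
reads. A companion generator draws coded OSPAF tables with known
population associations (φ per binary variable).

## Worked example

Simulate a 34-penalty study with a planted goalkeeper-strategy structure,
extract the pose metrics, and analyse:

```bash
penaltypose simulate --out study --seed 7 --n-penalties 34 --pixel-noise 1.0
penaltypose extract  --keypoints study/keypoints --corners study/corners.csv \
                     --annotations study/annotations.csv --out extracted
penaltypose analyze  --features extracted/metrics.csv --ospaf study/ospaf.csv \
                     --outcome gk_strategy --out report
```

which prints (abbreviated):

```
Strategy report: outcome=gk_strategy (positive level: kicker_dependent), alpha=0.05
n analysed = 34 (0 'unclear' rows excluded)

variable                    kind              stat        p   effect  class
run_up_speed                categorical      2.982   0.0842    0.296  moderate
gk_tactical_action          categorical     19.882   0.0000    0.765  strong*
...
alpha_gk                    numeric         -0.894   0.0000    0.894  strong*
...

notational model: chi2(1) = 22.504, p = 0.0000, accuracy = 88.2%
notational + pose model: chi2(2) = 47.134, p = 0.0000, accuracy = 100.0%
accuracy delta = +11.8 points
```

Screening retains exactly the planted structure: the goalkeeper's tactical
action (χ² = 19.9, V = 0.77, strong) and the anticipation angle
(r_pb = −0.89 — lower anticipation goes with a kicker-dependent keeper).
Adding the pose variable to the notational model lifts classification
accuracy by 11.8 points, the mixed-method gain the pipeline is built to
expose. Starred rows are retained at α = 0.05; the `report/` directory
holds the same report as JSON and text plus a run log.

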