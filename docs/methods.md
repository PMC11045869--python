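# Methods

## The estimation problem

A wrist smartwatch samples triaxial acceleration at 2 Hz and emits one
record per minute: the *average of PA* (PA_avg), the *variance of PA*
(PA_s), a step count, light-sensor fields, and wear status. The criterion
measurement is minute-averaged METs from indirect calorimetry (one MET =
3.5 ml O₂·kg⁻¹·min⁻¹ at rest). The task is to estimate each minute's METs
from the watch record plus gender and BMI, and to categorize the minute as
sedentary (SED, ≤ 1.49 METs), light (LPA, 1.50–2.99), moderate (MPA,
3.00–5.99) or vigorous (VPA, ≥ 6.00) activity.

## Per-minute features

For each axis the 119 consecutive acceleration differences are taken;
PA_avg is the mean of their absolute values on the axis where that mean is
largest (the dominant axis), and PA_s is the mean squared deviation of the
dominant axis's absolute differences from PA_avg, both with divisor 119.

Two deliberate choices here:

* **Absolute differences.** A signed sum of consecutive differences
  telescopes to (last − first)/119 and carries no activity information;
  the magnitude of each change is what measures movement, so absolute
  differences are used in both PA_avg and PA_s. This makes both features
  non-negative, invariant under constant offsets (gravity, sensor bias),
  and homogeneous under scaling (PA_avg of degree 1, PA_s of degree 2) —
  properties the test suite asserts.
* **Tie-break.** If two axes tie for the maximum, the fixed priority
  x > y > z makes the dominant axis deterministic.

The step counter (the watch firmware publishes no algorithm, so this is the
package's own) demeans each axis, takes the Euclidean magnitude, smooths it
with a centered 3-sample moving average, and counts local maxima that
exceed the median of the smoothed signal by ≥ 0.15 signal units with ≥ 2
samples (1 s) between peaks. All three parameters are configuration-exposed
(`StepDetectorParams`). Note that at 2 Hz a 1-step-per-second gait is at
the Nyquist frequency; sampled sinusoids at that rate are degenerate, so
step counts at realistic cadences are coarse. They serve as a monotone
activity feature, not as a validated pedometer.

Windows are half-open `[minute_start, minute_start + 60 s)` and must hold
exactly 120 samples; partial windows are rejected rather than padded.

## The hierarchical model

Stage 1 is a linear-kernel SVM over five features — log(1+PA_avg),
log(1+PA_s), log(1+steps), gender (male = 1), BMI — with three targets:
SED, LPA, and MVPA (moderate and vigorous collapsed; three intensity
classes are separable from wrist features where four are not). log(1+x) is
used rather than log x because sedentary minutes legitimately contain exact
zeros. Continuous features are standardized with training-set mean/SD
(stored in the model); the gender code is left as 0/1.

* Multi-class strategy: one-vs-rest; ties broken by the larger decision
  margin, then by class order SED < LPA < MVPA.
* Regularization: C is selected from {0.01, 0.1, 1, 10, 100} by 5-fold
  cross-validation **grouped by participant** (never fewer folds than
  participants), scoring macro (balanced) accuracy; ties go to the smaller
  C. Grouping mirrors the participant-level train/test split and prevents
  within-person leakage from inflating the CV score.

Stage 2 fits one ordinary-least-squares regression (intercept + the same
five standardized features) per intensity class, on the minutes whose
*true* class matches; at inference the regressor indicated by the
*predicted* class is applied. Fitting on true classes keeps classifier
error out of the regression estimates; applying by predicted class is the
only option available at deployment, when truth is unknown. Estimated METs
are clamped at a physiological floor of 0.5 (OLS can extrapolate below
rest), and categorized with the four cut-points.

Adults and children are trained and evaluated separately; the model is
serialized as versioned JSON holding the hyperplanes, regression
coefficients and standardization constants, so a round-trip is bit-exact.

## The trial simulator

The generator emulates a sequential activity calibration study:

* **Cohorts.** 24 adults / 18 children by default; demographics drawn from
  truncated normals around cohort means ± SD (adults: age 24.9 ± 2.6 within
  21–34 y, height 169.2 ± 7.2 cm, weight 61.7 ± 8.7 kg; children: 12.3 ±
  1.0 within 9–13 y, 160.5 ± 10.3 cm, 52.6 ± 12.5 kg), gender exactly
  balanced. BMI is always derived, never stored.
* **Protocol.** Seven activities in fixed sedentary-to-vigorous order —
  sitting, standing still, slow walking, quick walking, stairs, jogging,
  run/rope skipping — children omit jogging. Each trial lasts 14–16 min
  (uniform); the first 3 min (warm-up) and last 1 min are excluded from
  analysis.
* **Criterion METs.** Each trial draws one participant steady state from
  the activity's calibrated Normal(mean, SD) — e.g. adult sitting
  1.01 ± 0.13, adult run/rope skipping 9.40 ± 3.74, child stairs
  6.01 ± 2.18 — truncated below at 0.5 METs. Warm-up minutes ramp linearly
  from 1.0 toward the steady state (their shape is unidentifiable from
  study reports since they are always discarded; the ramp exists so the
  trimming rule has something real to remove). Later minutes add
  Normal(0, 0.1·SD) noise: most of the published per-activity SD is
  attributed to between-participant steady states, and the 0.1 within-trial
  factor is a free, configuration-exposed parameter.
* **Accelerometry.** The minute's dominant-axis signal is a sinusoid at
  the activity's cadence frequency (capped just below the 1 Hz Nyquist
  limit; 0.25 Hz postural sway when cadence is zero) with amplitude
  0.1·(MET − 1) signal units, clamped at zero, plus Gaussian jitter of SD
  0.02 per sample; the other axes carry half the amplitude at independent
  phases. This makes the extracted PA_avg monotone in expectation in the
  true MET, which is the premise of wrist-based MET estimation.
* **Quality flags.** Independent Bernoulli non-wear (p = 0.02) and
  unstable-energy-expenditure (p = 0.03) minutes, both configurable;
  flagged minutes are excluded like the trimmed ones.
* **Split.** Participant-level 70/30 train/test split, size rounded half
  up (24 → 17/7, 18 → 13/5). Every minute inherits its participant's
  assignment, so train and test participants are disjoint by construction.

Determinism: one master seed is expanded through `numpy` seed sequences
into per-participant substreams; the same seed reproduces a bit-identical
study, model and report.

### What the simulator does not emulate

The MET → wrist-amplitude link is a single clean deterministic function
plus small jitter. Real wrists differ in movement economy, wear position,
and activity style, so real features are far noisier *between people* than
the simulator's. Consequently the pipeline's near-perfect synthetic
accuracy (MAE ≈ 0.05–0.12 METs, AUC ≈ 1.0) is an upper bound that
demonstrates correctness of the machinery — not a claim about field
accuracy, which in comparable human validation studies sits near MAE
0.75–0.80 METs with AUC 0.85–0.98 depending on category. Passing tests
show the estimator recovers the generator's structure exactly when it is
realizable and degrades monotonically with noise; they cannot show
transportability to human data.

## Validation statistics

* **Per-category classification** (SED, MVPA, VPA, each one-vs-rest):
  the continuous ROC score is the estimated MET (negated for SED, where
  lower METs indicate the positive state) — a smooth score is required for
  a non-trivial ROC; sensitivity/specificity/Youden are computed at the
  categorized-estimate operating point. CIs: Wilson for proportions; for
  AUC, the Mann–Whitney estimator with ties counted ½, DeLong placement
  variance, and a normal 95% CI clipped to [0, 1]. Cohort AUCs are
  compared with an unpaired z-test on the DeLong variances (cohorts are
  independent samples).
* **Errors:** MAE, MAPE (percent of the criterion value), RMSE, pooled
  over minutes; the "±" companion reported beside each pooled value is the
  SD of the per-minute error magnitudes, and per-participant MAE/RMSE
  (mean ± SD across participants) are reported separately and labeled.
* **Agreement:** Bland–Altman on d = estimated − true (bias = mean d,
  LoA = bias ± 1.96·sample SD of d, so the LoA midpoint is identically the
  bias); ICC(2,1) — two-way random effects, absolute agreement, single
  measures — computed from the row/column/error mean squares; Spearman
  rank correlation with average ranks for ties.
* The difference direction (estimated − true) is a convention, stated on
  every output.

Evaluation refuses to run if any test participant contributed to training
(leakage error).

## Numerical and testing choices

* OLS is solved by `numpy.linalg.lstsq` (SVD). The test suite checks
  coefficient-level equality with a closed-form normal-equations solve on
  a well-conditioned construction; on simulated studies the sedentary
  class design is nearly collinear (all sedentary minutes have near-equal
  features), where coefficients are not identified even though fitted
  values are — there the suite compares fitted values instead.
* ICC is cross-checked against an independent two-way ANOVA implementation
  (pingouin's ICC(A,1)) and a hand-computed mean-squares fixture.
* AUC is cross-checked against brute-force pairwise concordance counting.
* Stochastic end-to-end tests use scaled-down studies (8–10 participants,
  10 seeds) — cohort size only changes Monte-Carlo resolution, not the
  logic under test; the acceptance script uses the full 24/18 cohorts.
* Step-counter unit tests use an analytically tractable bump-train signal
  (one 2-sample bump per 3 s) rather than a 1 Hz sinusoid, which is
  degenerate at the 2 Hz sampling rate.

## Known limitations

* Acceleration units are arbitrary: published feature magnitudes from any
  particular device cannot be matched, only structure.
* The simulator's noise model is stationary within a trial; real
  calorimetry drift, transitional minutes between activities, and
  free-living (non-protocol) behavior are not modeled.
* The step counter is a plausible placeholder at 2 Hz, not a validated
  gait algorithm.
* MAPE is reported over all minutes; criterion METs are bounded below by
  the 0.5 floor so no near-zero denominators occur, but MAPE still weights
  sedentary minutes more heavily than vigorous ones.
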