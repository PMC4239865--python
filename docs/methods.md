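# Methods

## Detection model

The detector consumes three vertical-axis channels from one body-worn
IMU, sampled at 100 Hz: angular velocity ω (raw gyroscope, deg/s), fused
orientation θ (deg), and magnetometer heading (arbitrary units).  θ and
the heading are zero-referenced by subtracting their mean over a
baseline window at the start of the trial (default: first 1.0 s, while
the subject stands; configurable).  Baseline subtraction is idempotent
and never touches ω.

A turn is declared at the first monitored sample where an enabled
criterion is *strictly* exceeded: |ω| > `gyr_thresh` or |θ| >
`angle_thresh`.  Monitoring starts at `search_start_ms` (default: the
end of the baseline window).  The angle is measured relative to the
trial start, not a running pre-turn heading, so heading drift during
straight walking is a genuine false-positive mechanism.  The batch
implementation is a vectorized linear scan; the streaming implementation
consumes one sample at a time, uses only past samples, and latches after
firing.  The two are equivalent by construction and property-tested to
agree exactly.

Sign convention everywhere: positive vertical-axis angle/velocity =
left turn (counterclockwise viewed from above).

## Threshold training

Given a database of labelled trials, a threshold pair is scored by an
error count: a turn trial detected within `tolerance_ms` (default
500 ms) of its reference onset adds 0; detected outside it adds the
premature/late weight; undetected adds the false-negative weight; a
straight trial with any detection adds the false-positive weight
(weights default to 1, 1, 1).  The 500 ms tolerance bundles the maximum
useful reaction delay of an assistive device with the uncertainty of
manually annotated onsets; it is configurable, and error weights can be
skewed when an application cares more about, say, false negatives.

The cost is piecewise constant in (gyr_thresh, angle_thresh): raising a
threshold past successive running-maximum records of the rectified
signal moves the detection time through a finite set of sample times.
Two consequences drive the optimizer design:

- **Evaluation.** Each trial is reduced once to its record envelope
  (strictly increasing prefix-maximum values with their times); the
  detection time under any threshold is then a binary search, and whole
  candidate populations are scored with a handful of vectorized lookups
  per trial (`CostSurface`).  The vectorized path is property-tested to
  reproduce the direct per-trial path exactly.
- **Optimization.** Gradients do not exist and minima are flat
  plateaus.  `optimize_thresholds` runs a seeded differential-evolution
  search (vectorized, no polishing step) *and* a deterministic 50 x 50
  log-spaced grid scan of the search bounds — (0.5, 300] deg/s x
  (0.5, 180] deg — and returns whichever found the lower cost.  Among
  equal-cost grid points it returns the one nearest the plateau's
  log-space centroid: a maximum-margin tie-break that keeps thresholds
  away from plateau edges, where small shifts in a new subject's noise
  floor or turning speed flip trials into errors.  Results are
  deterministic given `optimizer_seed`.  Because minima are flat, the
  *cost* of the returned pair is well-defined but the pair itself is
  not unique; downstream code and tests rely on the cost, never on
  threshold identity.

## Direction and amplitude classification

At T = onset + offset (offsets 0–500 ms are evaluated), the feature
triple (ω, heading, θ) is read at the nearest sample.  Direction
(left/right) uses signed features; amplitude (22/45/90) uses absolute
values.  The classifier is linear discriminant analysis with the
Gaussian equal-covariance class model kept explicit: per-class means,
prior-weighted pooled within-class ML covariance, empirical priors.
Prediction maximizes the linear discriminant score; exact ties break to
the first label in sorted class order.  A singular pooled covariance
(possible in degenerate synthetic cases, never in realistic data) is
ridged with 1e-6 x trace/3 on the diagonal.

Training features are extracted at the *reference* onset + offset (the
clean supervised signal); prediction uses the *detected* onset + offset.
One model is trained per (location, offset, task).  The systematic lag
between detected and reference onset therefore shifts test features
relative to the training distribution — a deliberate fidelity to how
such a system must operate online, and the main reason amplitude
accuracy at the moment of onset is near chance and grows with offset.

## Evaluation protocol

Per-trial outcomes: CD (detected within tolerance), PLD (outside), FN
(turn missed), FP (straight trial with detection), TN.  CD/PLD/FN
percentages share the turn-trial denominator and sum to 100 exactly; FP
uses the straight-trial denominator and is reported absent (not 0) when
a fold has no straight trials.  DIFF is the mean signed detected −
reference over detected turn trials; positive = late.

Two leave-one-out schemes: *within-subject* (per subject, leave one
trial out; that subject's outcomes are pooled into percentages, then
percentages are averaged unweighted across subjects) and
*subject-independent* (leave one subject out; train on the other
subjects).  Classification accuracy is computed only over correctly
detected trials, per offset.  Amplitude-subset experiments drop 22- (or
22- and 45-) degree turns from both training and test folds while
always retaining straight trials.

## Synthetic cohort

The generator stands in for the study's (undeposited) recordings and
defines the package's study conditions.

**Protocol.**  Each subject: 7 blocks x a seeded random permutation of
the 7 travel paths (49 trials).  Default cohort: 10 subjects, seed 1.

**Timing.**  Targets: trial duration 16.4 ± 2.2 s, walking begins
8.3 ± 2.3 s after trial start, turn onset at 10.2 ± 2.3 s.  To honor the
ordering constraints (stand → walk → turn → ≥ 1 s of post-turn signal)
without biasing the means, onset is drawn marginally N(10.2, 2.3²)
(truncated ≥ 4 s); walk start = onset − gap, gap ~ N(1.9, 0.7²)
truncated ≥ 0.4 s; duration = onset + post, post ~ N(6.2, 1.5²)
truncated to fit the turn plus a 1.2 s margin.  Realized *means* match
the targets (verified by a sampling test); the realized SDs of walk
start and duration differ slightly from the marginal targets — a known,
accepted property of the construction.

**Turn kinematics.**  Per segment, θ(t) = A·L((t − t0 − lag)/τ) with L
the standard logistic, A the signed amplitude, and closed-form
ω_peak = A/(4τ).  Ground-truth onset is the instant the lag-free
logistic reaches 5% of A (the documented proxy for an expert-annotated
"turn begins" instant); t0 = onset + logit(0.95)·τ.  Healthy peak
speeds {22°: 40, 45°: 80, 90°: 75 deg/s} put 45/90-degree turns above
and 22-degree turns below typical trained gyro thresholds, so small
turns are caught later by the angle criterion — the central mechanism
the detector exploits.  A per-subject speed factor (uniform 0.9–1.35 on
τ) makes optimal thresholds subject-dependent.  The amputee profile
lowers peaks to {22°: 20, 45°: 33, 90°: 48 deg/s}; its 22/45-degree
turns fall below healthy-trained gyro thresholds.

**Segment lags.**  head −200 ms, upper back 0, lower back +30, thigh
+100, shank +150, foot +200 — ordered to encode the top-down turning
strategy of healthy adults.  The magnitudes are literature-motivated
placeholders, not measured values, and are configurable.

**Nuisance structure.**  Per-step yaw oscillation (1.0–2.5 deg by
location, ~1.9 Hz, per-step amplitude jitter interpolated smoothly so
its derivative stays physical), a heading random walk
(0.4 deg/sqrt(s)) during walking, standing sway (0.3 deg), white gyro
noise (4 deg/s), magnetometer gain 1 with extra disturbance at the feet
(5 units), and anticipatory head glances (probability 0.6, 10–30 deg,
toward the turn target) that make the head channel realistically
unreliable for onset detection.  `GeneratorConfig.noise_free()` turns
all nuisance terms off for closed-form parameter-recovery tests.

**What the generator does not emulate:** sagittal-plane gait events,
accelerometer channels, optical-reference noise and expert
disagreement, on-the-spot turning strategies, and real segment-lag
variability.  Passing tests therefore demonstrate the pipeline's
correctness and its qualitative behavior under top-down turning with
realistic noise floors — not performance figures transferable to human
recordings.

## Numerical choices and degenerate inputs

- Strict inequality at thresholds: a sample exactly equal to a
  threshold does not fire (tested).
- Sample k is at k/f_s seconds, 0-based; times are ms from the first
  sample; feature extraction uses the nearest sample.
- Simultaneous gyro+angle crossing is labelled trigger "both"; the
  onset time is unaffected.
- Empty training database: cost defined as 0 (logged); optimization
  refuses it.
- Averages across subjects are unweighted; within-subject outcomes are
  pooled per subject *before* percentage computation.
- All randomness flows from a single seed; per-subject generator
  streams are derived via CRC32 of the subject id, so sessions are
  reproducible independently of cohort size.

## Problem sizes used in the shipped analyses

The default cohort (10 x 49 trials, six sensor locations) is used for
threshold training, both crossvalidation schemes, and the qualitative
ordering checks; streaming/batch agreement uses 1000 generated trials;
the discriminant's Bayes-gap check uses 100,000 Monte-Carlo points.
These sizes make every analysis exactly reproducible in minutes on a
single CPU while keeping per-criterion counts large enough (420 turn
trials per scheme) for stable percentages.

## Known limitations

- The generator's separability makes trunk-sensor detection saturate
  (CD ≈ 100%) under trained thresholds; human recordings show lower
  ceilings.  Qualitative orderings (trunk > legs > head for onset;
  combined ≥ single criteria; small turns dominate errors) are the
  meaningful comparisons.
- Within-subject amplitude classification inherits a train/test feature
  misalignment from the detected-onset lag (see above) and can trail
  the subject-independent figures on synthetic data.
- The optimizer returns one point of a flat minimizing plateau;
  different but equally optimal thresholds are possible and expected.
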