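# Methods

This note documents the models and procedures implemented in
`armscore`, the parameters that matter, the synthetic-cohort generative
model, and the numerical and design choices made where the published
pipeline description left the design open.

## Signal processing

Trials are segmented to the `[start, end)` marker window first and
filtered second.  Axis signals are low-pass filtered at 8 Hz and then
high-pass filtered at 0.25 Hz, both 6th-order Butterworth, applied
forward–backward (zero phase).  Zero-phase application doubles the
effective order, so the cascade's transition bands are steeper than the
nominal design; this is intentional — offline feature extraction should
not phase-distort the waveforms.  The 0.25 Hz high-pass doubles as the
gravity/posture remover; no explicit gravity-vector estimation is done.

Numerics: a single `sosfiltfilt` pass is not exactly invariant under
time reversal, because its edge conditioning is one-sided relative to
the very long transient of the 0.25 Hz stage (time constant ≈ 0.6 s ×
order).  We therefore use a *symmetrized* zero-phase operator — the
average of the forward–backward and backward–forward passes, with
padding widened to min(n−2, 300) samples — which is exactly
time-reversal symmetric and has the same frequency response.

Velocity and displacement are cumulative trapezoidal integrals of the
filtered acceleration; the same 0.25 Hz high-pass is re-applied after
each integration to suppress integration drift (the published
description derives these series without saying how drift was
controlled).  Jerk is the central finite difference.  Magnitudes are
per-sample Euclidean norms across axes, so they are invariant to sensor
axis rotation.  Units follow the g-input convention (acceleration in g,
velocity in g·s, displacement in g·s², jerk in g/s); features are
scale-consistent so no conversion to SI is needed.

## Features

Per placement × {displacement, velocity, acceleration, jerk} magnitude:
min, max, mean, RMS, dominant-frequency ratio, skewness, excess
kurtosis, entropy.  Conventions chosen where the literature leaves
options open:

* **Entropy**: Shannon entropy (nats) of a 16-bin histogram of the
  min–max normalized series; constant series → 0.
* **Skewness/kurtosis**: bias-corrected sample skewness and *excess*
  kurtosis; near-constant series → 0.
* **Dominant-frequency ratio**: rectangular-window periodogram, peak
  power ÷ total power with the DC bin excluded from both (the
  high-pass already removed DC; including it would create degenerate
  peaks).  In (0, 1]; ≈ 1 for a pure tone.
* **Correlations**: both readings of "correlations between axes" are
  emitted — intra-sensor inter-axis correlations of the filtered
  acceleration, and inter-sensor correlations of the acceleration
  magnitudes for all placement pairs (the latter capture relative
  segment motion such as compensatory trunk lean).  Correlation with a
  constant series is defined as 0.
* **Jerk scalar** (feature family 4): RMS of the jerk magnitude.
* **Duration**: marker-window length / fs.  Sub-movement-level
  durations would require a sub-movement segmentation algorithm that
  the published description does not provide; total trial duration is
  used, a known fidelity gap.

With the default six-sensor montage (chest, affected arm, both wrists,
affected thumb and index) this yields 222 features per trial.

**CFS.**  Feature selection maximizes Hall's merit
`M(S) = k·r̄_cf / sqrt(k + k(k−1)·r̄_ff)` by best-first search over
subsets: nodes are expanded in merit order, each expansion evaluates
all single-feature additions (vectorized incrementally), the frontier
keeps the 50 best children per expansion, and the search stops after 5
consecutive expansions that fail to improve the incumbent (hard cap
2000 expansions).  On ≤ 12 features this matches exhaustive search in
well over 95% of random instances.  Selection always runs inside the
training fold only — never on data from the held-out subject.

## Forests

All forests are bagged CART regression trees (scikit-learn trees under
a package-owned bootstrap layer) with `max_features = p/3` (regression
convention), unlimited depth, minimum leaf 1, prediction = tree mean.
These tree parameters are not specified in the published pipeline and
follow common random-forest defaults; all are exposed in config.

**Balanced bootstrap** (the core of methods 3 and 4): each tree's bag
draws an equal number of samples with replacement from each nonempty
severity class (FMA ≤ 30, 30–38, 38–47, 47–56, > 56).  The default
draw is `round(n/k)` per class (`"mean-class"`), which *rebalances the
training set without shrinking it* — the bag stays near the ordinary
bootstrap size while every severity band gets equal weight.  The
classical down-sampling convention (`"min-class"`, smallest-class size)
is available but not default: with 2–4 subjects in the extreme classes
it shrinks bags to ~25% of n, and in our cohort-level measurements that
cost more overall accuracy than the rebalancing gained.  Empty classes
are skipped with a warning; a single-class sample degenerates to a
plain bootstrap.

**Stacking inputs.**  The aggregator forest is trained on per-task
estimates of the *training* subjects.  Using resubstitution predictions
would feed the aggregator nearly noise-free inputs unlike anything it
sees at test time; a full inner cross-validation would multiply the fit
count by the fold count.  We use out-of-bag (OOB) predictions: for each
training row, the mean over trees whose bag excluded that row.  This
gives test-like error structure at zero extra fits.  Rows present in
every bag (possible with a singleton class) fall back to the ensemble
prediction.

## Score estimators

* **FAS**: per-task 100-tree forests on per-repetition rows; test
  repetitions predicted, averaged per task, summed over the 8 tasks,
  then `FAS_Total = (Σ·1.78 + 2.97)/15`, clipped to [0, 5].  All eight
  tasks are required — the calibration constants were derived for the
  full battery.
* **Method 1**: OLS of true FMA on true total FAS over training
  subjects, evaluated at the held-out subject's sensor-estimated FAS;
  fit per fold (whether the original was fit once or per fold is
  unstated; per-fold is the leakage-free choice).
* **Method 2**: per-task 100-tree plain-bootstrap forests → repetition
  averaging → 8-vector → 50-tree aggregator.
* **Method 3**: method 2 with balanced bags in the per-task forests
  *and* the aggregator (aggregator treatment is unstated in the
  published description; uniform treatment is the simpler rule and is
  switchable via `balance_aggregator`).
* **Method 4**: method 3 with the sensor-estimated FAS appended both to
  every per-task feature vector and to the aggregator input ("an input
  was added to each RF" read literally).

Estimates are clipped to the scale ranges ([0, 5], [0, 66]) after
prediction; forest predictions are bounded by the training target range
before clipping by construction.

**FAS estimates feeding methods 1 and 4.**  Default: one shared LOSO
pass — each subject's FAS estimate comes from forests never trained on
that subject, computed once, then reused in every outer fold.  This is
the design the published pipeline describes (FAS estimated by LOSO,
then used as an input), and it never exposes a subject's own labels to
its estimate; the residual subtlety is that the *features* of the
current test subject participated in training the FAS models of the
other subjects.  A fully nested mode (`fas_hat_mode="nested"`)
re-estimates training subjects' FAS inside each outer fold, excluding
the test subject entirely; it multiplies the FAS-stage fits by the
cohort size for a difference we could not distinguish from forest
resampling jitter on small cohorts, so the shared pass is the default.

## Evaluation

LOSO is the primary harness: one fold per subject, everything fitted
per fold.  Metrics: RMSE, r² = 1 − SSE/SST (SST about the truth mean;
undefined for constant truth), bias = mean(estimate − truth); these
satisfy RMSE² = bias² + error variance.  Per-severity-class analysis
groups *signed* errors (estimate − truth, so overestimation of severely
impaired subjects appears as a positive median in class 1) by the
*true* score's class and reports median/Q1/Q3 with linear-interpolation
(type-7) quantiles.  Method comparisons within a class use two-sided
paired t tests on per-subject absolute errors ("improvement"
semantics); degenerate cases (n < 2, zero-variance differences) are
reported as NaN rather than fabricated p-values.

A record-level k-fold mode (`first_module_cv(mode="kfold")`) exists as
a deliberately optimistic comparator: it splits individual repetitions,
so each subject's other repetitions leak into training, and with
`leaky_selection=True` feature selection additionally sees the full
data.  On small noisy cohorts it scores visibly higher than LOSO —
the classic overfitting trap the subject-level design avoids.

## Synthetic cohort

The generator emulates the statistical structure the estimators
exploit, with impairment `s = (66 − FMA)/66` driving every signal
property monotonically:

| parameter | default | meaning |
|---|---|---|
| `fs` | 50 Hz | sampling rate (ample for an 8 Hz low-pass pipeline) |
| `fma_class_weights` | (4, 8, 15, 7, 3) | severity-class mix; deliberately nonuniform, a handful of subjects in the extreme classes |
| `reps_per_task` | 2 | repetitions per task (up to 3 supported) |
| `duration_gain` (a1) | 1.2 | slowing: duration × (1 + a1·s) |
| `tremor_gain` (a2) | 0.20 g | tremor amplitude at s = 1, random frequency in `tremor_band` (3.5–7 Hz) |
| `submovement_gain` (a3) | 6 | mean extra sub-movement pulses at s = 1 (fragmentation → jerk) |
| `trunk_gain` (a4) | 0.9 | chest coupling to the affected wrist at s = 1 (compensatory lean) |
| `noise_sd` | 0.02 g | white measurement noise |
| `tempo_sd`, `heterogeneity_sd` | 0.15, 0.5 | subject-level lognormal variability of tempo and of tremor/fragmentation propensity |
| `fas_subject_sd`, `fas_task_sd` | 0.35, 0.2 | FAS label noise: shared per-subject rater bias + per-task noise |

Movements are sums of minimum-jerk-like bell pulses (derivative-of-
Gaussian acceleration shapes): two stereotyped reach-and-return pulses
per task plus `Poisson(a3·s·heterogeneity)` narrow fragments.
Incidental movements (trunk sway, the unaffected limb) use random pulse
times so they do not spuriously correlate with the performing limb.
The chest carries `a4·s` of the affected-wrist motion (including half
of the transmitted tremor) on top of its own sway.  Per-task true FAS
is a monotone map of s with task offsets, the subject's rater bias, and
small noise, clipped to [0, 5]; across a cohort this yields a strong
but imperfect FMA–FAS association (Pearson r ≥ 0.8), which is what
bounds method 1's accuracy from above.

Determinism: subject i is a pure function of (config, i) via seed
substream `SeedSequence([seed, i])`; growing a cohort never changes
earlier subjects.

Calibration: the impairment coefficients and subject-heterogeneity
levels were set so that the proposed method recovers FMA with r² ≈ 0.8
on a default 40-subject cohort — informative but not trivial, roughly
the accuracy regime reported for real cohorts of this size.  The
generator does *not* model: object-specific manipulation dynamics
(can, pencil, cards, key), sensor orientation drift or calibration
error, non-stationary tremor, spasticity-induced co-contraction
patterns, or missing/failed task attempts.  Passing synthetic tests
therefore demonstrates that the pipeline recovers scores when its
assumed signal–impairment relationships hold; it does not certify
clinical accuracy, which can only be established against clinician-
scored recordings.

## Problem sizes

Default experiment sizes were chosen for a single-CPU workflow: the
standard evaluation cohort is 40 subjects × 8 tasks × 2 repetitions at
50 Hz (~3–8 s active movement per trial); stochastic acceptance
properties average 5 seeds; the overfitting demonstration uses a
14-subject noisy cohort.  A full five-method LOSO evaluation of a
40-subject cohort takes roughly two minutes on one CPU.

## Known limitations

* The per-task supplementary accuracy breakdown of the original study
  is not reproduced (its per-task table is not in the main text).
* Total duration stands in for sub-movement durations (above).
* Whether severity classes should be formed by true or estimated FMA
  for the per-class analysis is unstated; true-score grouping is used.
* The printed age, chronicity, and discharge-FAS t statistics of the
  reference cohort table are not recoverable from the printed summary
  statistics under either pooled or Welch conventions (presumably
  computed from unrounded data); they are stored for reference but
  excluded from exact-reproduction checks.  The inpatient-setting
  chi-square recomputes to 6.3450 vs a printed 6.35 — agreement to one
  unit in the last printed digit.
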