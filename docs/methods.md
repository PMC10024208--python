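# Methods

This note records the models, parameter choices and numerical conventions
behind wearcirc, and what the synthetic world does and does not establish.

## Synthetic wearable world

Every stage of the pipeline is exercised on simulated cohorts of 9–12 year
olds wearing a consumer wrist tracker. The generator is a *stated world*:
its defaults are fixed in `src/wearcirc/defaults.yaml` and are not free
knobs for making tests pass.

**Subjects.** Sex, age (144 ± 8 months), height (150 ± 8 cm) and weight
(47 ± 9 kg) are drawn per subject; the binary diagnosis is i.i.d.
Bernoulli(prevalence). Positive subjects are drawn male with probability
0.696 versus 0.507 for controls — child ADHD cohorts skew male, and sex is
a model input, so omitting this association would misstate the world being
emulated.

**Heart rate.** Per-minute HR is a 24-h cosine plus AR(1) noise:
`HR(t) = M + A·cos(2π(t − φ)/24) + ε(t)`, with subject-level
M ~ N(82.7, 6²) bpm, A ~ N(12, 3²) bpm, φ ~ N(15, 1²) h, a day-level MESOR
wobble of SD 1.5 bpm, and AR(1) noise with stationary SD 9 bpm (chosen so
the cosinor goodness of fit lands near 45 %). The cosine form makes the
cosinor stage's ground truth exactly recoverable at zero noise.

**Steps.** Zero during sleep; otherwise zero-inflated negative binomial per
minute with a cosine envelope peaking mid-afternoon. Step *rhythm* features
(cosinor, L5/M10/RA) are computed on hourly step totals, which puts MESOR
near (daily steps)/24 and M10 near the peak hourly total — the scale on
which these metrics are conventionally reported for count data.

**Sleep.** One consolidated main episode (onset ~22:00 ± 45 min between
subjects, duration 8.2 ± 0.6 h, nightly jitter ~20–25 min) plus an
afternoon nap on 35 % of days (start uniform in 12:00–17:00, duration
lognormal, median 45 min). Each day is a circular 24-h record: the main
episode appears as late-evening plus early-morning in-bed epochs of the
same date. The 30-s record scores each in-bed epoch wake (p = 0.133) or a
sleep stage (light 0.587, deep 0.190, REM 0.223 conditional on sleep) in
geometric runs (mean 20 epochs); the 60-s record scores
asleep/restless/awake at 0.939/0.056/0.005, giving a 60-s sleep quality
near 94 %.

**Activity and calories.** METs are a sedentary baseline (1.15 ± 0.25,
floored at 1.0, exactly 1.0 asleep) with ~6 activity bouts/day
(exponential durations, mean 35 min; lognormal intensity, median 3.8 METs).
Intensity is the ordinal MET bin. Calories are METs × 3.5 × weight(kg)/200
kcal/min — the standard indirect-calorimetry conversion, since consumer
devices do not publish their calorie model.

**Group effects.** The effect map shifts positive subjects' latent
parameters in units of the between-subject SD: MESOR +0.23, sleep duration
−0.11, step level +0.09, activity-bout rate +0.16, nap duration 0. These
standardized sizes reproduce the direction and approximate magnitude of the
group differences a child ADHD cohort shows on the observed features
(e.g. +1.7 bpm MESOR, −4 min in-bed sleep).

**Missingness.** Whole hours of per-minute wear are blanked independently
with the configured rate (default 5 %); sleep epochs are unaffected. NaN is
the only missing marker; nothing is silently zeroed.

**What the generator does not emulate.** Device bias and drift, school-day
versus weekend structure, seasonal change, proprietary staging error,
between-feature correlation beyond what the latent parameters induce, and
subject-level rhythm instability — the synthetic IS is therefore higher
(~0.8) than real child actigraphy (~0.2). A green test establishes that the
algorithms are correct on a world with known truth, not that the published
real-data performance is reproduced; the real cohort is not accessible from
this package.

## Preprocessing conventions

- Wear validity: an hour is valid with **≥ 30** worn minutes, a day with
  **≥ 5** valid hours (the boundary counts as valid; "less than" is read
  strictly). A worn minute is one with a heart-rate sample.
- Minute intervals are half-open [t, t+1); epochs belong to the day on
  which they start.
- Main sleep is the longest in-bed block (circular day) overlapping
  20:00–10:00; equal-length ties go to the earlier start. Other blocks
  ≥ 10 min are naps; shorter fragments are ignored. Bedtime is the union of
  sleep windows, daytime its complement, so the two partition the 1440
  minutes exactly.
- 30-s sleep features: plain durations are epoch count × 0.5 min; the
  "stage" variants are raw epoch counts (exactly 2× the minutes — the two
  scales both appear in consumer-device exports). Deep/light/REM rates are
  % of asleep time; the wake rate and quality are % of in-bed time.
  Quality is reported missing, never 0, when no in-bed time exists. 60-s
  quality = asleep/(asleep+restless+awake) × 100.
- BMR differences are equation_BMR − measured daily kcal, so consumption
  above the estimate is negative. Forms used: revised Harris-Benedict
  (Roza–Shizgal), Mifflin-St Jeor, Katch-McArdle with Boer lean body mass
  (no body-composition measurement is available).
- MET cutoffs: sedentary < 1.5 ≤ light < 3 ≤ moderate < 6 ≤ vigorous,
  configurable.

## Circadian metrics

- Cosinor: OLS on `y = M + β·cos(2πt/τ) + γ·sin(2πt/τ)`; amplitude
  √(β²+γ²); acrophase = clock time of the fitted maximum wrapped to
  [0, 24); gof = 100·R², clipped to [0, 100]. Requires ≥ 3 distinct time
  points spanning ≥ τ/2; a constant series returns amplitude 0, gof 0.
  Acrophase is always reported as hour-of-day, for both HR and steps.
- IS = variance of the mean 24-h profile over total variance (computed with
  missing-adjusted counts); IV = mean squared successive difference over
  variance (pairs spanning a missing hour are skipped). Zero-variance
  records give NaN. L5/M10 enumerate all 24 wrap-around windows on the mean
  profile; windows with > 50 % missing hours are disqualified. L5 and M10
  are activity *levels* (the only reading under which RA = (M10−L5)/(M10+L5)
  is well defined).
- Cosinor and L5/M10/RA are per-day features; IS/IV require several days
  and are computed once per subject on the pooled hourly record of valid
  days, then broadcast to that subject's entries.

## Feature registry

Exactly 64 circadian features in a fixed order (see
`assembly.FEATURE_REGISTRY`), plus sex. Sixty-two are the standard
daily-summary/rhythm set; the remaining two are main-sleep onset and offset
hour, standard wearable sleep-timing features. One training entry = one
valid subject-day; entries inherit the subject's diagnosis via the unique
subject identifier. Missing values stay NaN at assembly; models that cannot
digest NaN (random forest) receive partition-level training-median
imputation at fit time, and the boosted-tree learners handle NaN natively.

## Cohort statistics

Normality is screened per group with the Kolmogorov-Smirnov test against a
normal with estimated parameters (Lilliefors correction) at α = 0.05; both
groups normal → pooled-variance t test, otherwise Mann-Whitney U, always
two-sided. The sex row uses a chi-square test on the 2×2 count table.
Zero-variance features are reported with a missing p value rather than a
placeholder. Tests run on per-day entries; within-subject correlation is
accepted (and makes the per-day p values anticonservative for
subject-level effects — a deliberate, documented simplification; the null
calibration test therefore uses one-day-per-subject cohorts). No
multiple-testing correction is applied.

## Imbalanced modelling

- Split: stratified 70/10/20. Default unit is the **subject** — all of a
  child's days land in one split, preventing identity leakage; entry-level
  splitting is available as an option. Splits with zero positives are
  refused. Each of the repetitions re-draws the split by default
  (configurable).
- SMOTE: synthetics are x + u·(nn − x), u ~ U(0,1), nn among the k = 5
  nearest minority neighbours under pairwise-complete Euclidean distance on
  standardized features (distances rescaled by the shared-dimension count).
  Where the neighbour lacks a feature the synthetic inherits x's value, so
  no value is invented for an unobserved dimension. k is reduced with a
  warning when the minority is too small.
- Ensemble: N = 10 stratified partitions; per partition the minority is
  oversampled ×(1 + 2) and the majority undersampled to a 1:1 ratio; one
  base learner per partition; ensemble probability is the partition mean.
  Families: random forest (100 trees), depth-wise boosted trees
  (max depth 6) and leaf-wise-style boosted trees (31 leaf nodes), both at
  100 boosting iterations.
- Metrics at threshold 0.5 (no threshold selection is assumed; a validation
  Youden threshold can be passed explicitly): sensitivity, specificity,
  PPV, NPV from the confusion matrix, AUC as the rank statistic. PPV/NPV
  satisfy the Bayes identities against (sensitivity, specificity,
  prevalence) to machine precision. Aggregation over repetitions: mean,
  SD (0 by convention for a single run), and mean ± 1.96·SD/√R as the 95 %
  CI from the per-run value list. Best model = the single run with the
  highest validation PPV (ties to the earlier family/repeat).
- Seeding: one master seed; every repetition/family derives its seed
  through a fixed counter scheme (`SeedSequence([master, repeat, family])`),
  so reruns are bit-reproducible.

## Shapley attribution

The shap library is not a dependency; attribution uses a sampled
permutation Shapley estimator: for an evaluation point x, a random feature
order π and a random background point z from the data, features of x are
inserted into z in order π and each insertion's change in ensemble
probability is credited to that feature. Contributions telescope exactly to
f(x) − f(z) per sample; a constant feature receives exactly zero. Mean
|contribution| over (default) 40 evaluation points × 4 orders ranks the
features; the report lists the top 20. This estimator is noisier than exact
TreeSHAP but unbiased for the interventional Shapley value, and rankings
are stable under the default sample sizes.

## Design choices where the design was open

- 30-s sleep "quality" is defined as asleep/in-bed per day, averaged over
  days (mean of ratios, not ratio of means).
- The two registry features beyond the 62 standard ones are sleep onset and
  offset hour (see above).
- The L5 "hours" ambiguity is resolved as an activity level.
- `undersample_ratio`, `oversample_factor` and N follow common hyperSMURF
  practice (1:1, ×2, 10) and are configurable.
- Degenerate configuration (1 partition, no over/undersampling) reduces the
  ensemble to a single base learner, which is verified by test.

## Known limitations

- Per-day entries are correlated within subject; the group tests ignore
  this and no mixed model is provided.
- At smoke scale (200 subjects, ~14 positive) hold-out metrics are
  dominated by which 2–3 positive subjects land in the test split; only the
  study-scale cohort (≈ 1090 subjects) gives a stable above-chance AUC
  (~0.6) from the default planted effects. The published real-data AUCs are
  not reproducible from synthetic data and are out of scope.
- The generator's rhythms are more regular than real child actigraphy; IS
  in particular is optimistic.
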