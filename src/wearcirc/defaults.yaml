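# Versioned default parameters for the wearcirc pipeline.
# All tunable numbers live here; code holds no hidden constants.

cohort:
  n_subjects: 200
  prevalence: 0.0662        # rare-class fraction typical of child ADHD cohorts
  n_days_per_subject: 21    # three weeks of wear per subject
  missing_hour_rate: 0.05   # probability an hour of wear is lost
  seed: 0
  # Standardized mean shifts applied to positive subjects' latent generator
  # parameters (units of the between-subject SD of each parameter).
  effect_map:
    hr_mesor: 0.23          # positives run a slightly higher rhythm-adjusted HR
    sleep_duration: -0.11   # positives sleep slightly less
    steps_level: 0.09       # positives take slightly more steps
    activity_moderate: 0.16 # positives spend more time in moderate activity
    nap_duration: 0.0

population:
  male_fraction: 0.507          # among controls
  male_fraction_positive: 0.696 # positives skew male, as in child ADHD cohorts
  age_months_mean: 144.0    # ~12 y at the two-year visit
  age_months_sd: 8.0
  height_cm_mean: 150.0
  height_cm_sd: 8.0
  weight_kg_mean: 47.0
  weight_kg_sd: 9.0
  weight_kg_min: 25.0

rhythm:
  hr_mesor_mean: 82.7       # bpm, rhythm-adjusted mean heart rate
  hr_mesor_sd: 6.0          # between-subject
  hr_mesor_day_sd: 1.5      # day-to-day wobble within subject
  hr_amplitude_mean: 12.0   # bpm
  hr_amplitude_sd: 3.0
  hr_acrophase_mean: 15.0   # h, mid-afternoon HR peak
  hr_acrophase_sd: 1.0
  hr_noise_sd: 9.0          # AR(1) innovation scale chosen for ~46% cosinor fit
  hr_ar1: 0.5
  steps_level_mean: 15.0    # expected steps per awake minute at envelope centre
  steps_level_sd: 5.0
  steps_level_min: 2.0
  steps_acrophase_mean: 14.0
  steps_acrophase_sd: 1.5
  steps_envelope_depth: 0.9 # relative cosine modulation of the step rate
  steps_zero_prob: 0.5      # zero-inflation of per-minute step counts
  steps_dispersion: 0.35    # negative-binomial size parameter

sleep:
  onset_hour_mean: 22.0
  onset_hour_sd: 0.75       # between-subject
  onset_jitter_sd_min: 20.0 # night-to-night
  duration_hour_mean: 8.2
  duration_hour_sd: 0.6
  duration_jitter_sd_min: 25.0
  nap_probability: 0.35     # chance of an afternoon nap on any day
  nap_start_earliest_hour: 12.0
  nap_start_latest_hour: 17.0
  nap_duration_median_min: 45.0
  nap_duration_sigma: 0.4   # lognormal shape
  wake_epoch_prob: 0.133    # fraction of in-bed 30-s epochs scored wake
  stage_probs:              # conditional on asleep
    light: 0.587
    deep: 0.190
    rem: 0.223
  stage_mean_run_epochs: 20 # mean length of a stage run (30-s epochs)
  sleep60_asleep_prob: 0.939
  sleep60_restless_prob: 0.056

activity:
  bout_rate_per_day: 6.0
  bout_duration_mean_min: 35.0
  bout_met_median: 3.8      # lognormal median MET level of a bout
  bout_met_sigma: 0.35
  baseline_met: 1.15
  baseline_met_sd: 0.25

validity:
  min_worn_minutes_per_hour: 30   # exactly 30 worn minutes makes the hour valid
  min_valid_hours_per_day: 5      # exactly 5 valid hours makes the day valid

met_cutoffs:                # standard MET thresholds, configurable
  light: 1.5
  moderate: 3.0
  vigorous: 6.0

sleep_detection:
  main_window_start_hour: 20  # main sleep must overlap 20:00-10:00
  main_window_end_hour: 10
  min_nap_minutes: 10

circadian:
  l5_m10_max_missing_frac: 0.5  # window disqualified beyond this missing share

split:
  train: 0.70
  validation: 0.10
  test: 0.20
  unit: subject             # subject-level split avoids within-child leakage

hypersmurf:
  n_partitions: 10
  smote_k: 5
  oversample_factor: 2.0    # synthetics per real minority point
  undersample_ratio: 1.0    # majority:minority ratio per partition after resampling
  rf_n_estimators: 100
  gbt_max_iter: 100
  xgb_max_depth: 6          # depth-wise trees
  lgbm_max_leaf_nodes: 31   # leaf-wise-style trees

experiment:
  families: [rf, xgb, lgbm]
  n_repeats: 50
  threshold: 0.5
  redraw_split: true        # re-draw the 70/10/20 split every repetition

io:
  write_raw_streams: false  # long-format minute/epoch CSVs are large; the
                            # simulate subcommand always writes them

shap:
  n_eval: 40                # evaluation points sampled for attribution
  n_permutations: 4         # sampled feature orderings per point
  top_n: 20
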