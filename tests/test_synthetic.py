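"""Synthetic cohort generator: contracts, determinism, recoverable truth."""

import math
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

import wearcirc as wc
from wearcirc.synthetic import MINUTES_PER_DAY, _window_mask


class TestCohort:
    def test_zero_prevalence_yields_zero_positives(self):
        spec = wc.CohortSpec(n_subjects=100, prevalence=0.0, n_days_per_subject=1)
        profiles = wc.generate_cohort(spec)
        assert len(profiles) == 100
        assert sum(p.diagnosis == "positive" for p in profiles) == 0

    def test_positive_fraction_matches_binomial(self):
        # binomial oracle: observed fraction within 3 SDs of the prevalence
        p = 0.0662
        spec = wc.CohortSpec(n_subjects=10_000, prevalence=p, n_days_per_subject=1, seed=5)
        frac = np.mean([s.diagnosis == "positive" for s in wc.generate_cohort(spec)])
        assert abs(frac - p) < 3 * math.sqrt(p * (1 - p) / 10_000)

    def test_determinism(self):
        spec = wc.CohortSpec(n_subjects=50, prevalence=0.2, n_days_per_subject=1, seed=3)
        assert wc.generate_cohort(spec) == wc.generate_cohort(spec)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_subjects=10, prevalence=-0.1),
            dict(n_subjects=10, prevalence=1.2),
            dict(n_subjects=0, prevalence=0.5),
            dict(n_subjects=10, prevalence=0.5, n_days_per_subject=0),
        ],
    )
    def test_invalid_spec_rejected(self, kwargs):
        with pytest.raises(ValueError):
            wc.CohortSpec(**kwargs)

    def test_profiles_have_positive_anthropometrics_and_unique_ids(self):
        spec = wc.CohortSpec(n_subjects=200, prevalence=0.1, n_days_per_subject=1, seed=1)
        profiles = wc.generate_cohort(spec)
        ids = {p.subject_id for p in profiles}
        assert len(ids) == 200
        assert all(p.age_months > 0 and p.height_cm > 0 and p.weight_kg > 0 for p in profiles)


class TestDayStreams:
    def _params(self, **over):
        base = dict(
            hr_mesor=80.0,
            hr_amplitude=12.0,
            hr_acrophase=14.0,
            hr_noise_sd=0.0,
            hr_ar1=0.5,
            steps_level=12.0,
            steps_acrophase=14.0,
            sleep_onset_hour=22.0,
            sleep_duration_hour=8.0,
            nap_probability=0.0,
            nap_duration_median_min=45.0,
            activity_bout_rate=5.0,
        )
        base.update(over)
        return wc.SubjectParams(**base)

    def test_noiseless_hr_is_exact_cosine(self, profile, default_cfg):
        cfg = dict(default_cfg)
        cfg["rhythm"] = {**cfg["rhythm"], "hr_mesor_day_sd": 0.0}
        cfg["sleep"] = {**cfg["sleep"], "onset_jitter_sd_min": 0.0, "duration_jitter_sd_min": 0.0}
        day = wc.generate_day_streams(profile, 0, self._params(), seed=1, cfg=cfg)
        t = (np.arange(MINUTES_PER_DAY) + 0.5) / 60.0
        expected = 80.0 + 12.0 * np.cos(2 * np.pi * (t - 14.0) / 24.0)
        np.testing.assert_allclose(day.hr, expected, atol=1e-9)

    def test_steps_zero_during_sleep_window(self, profile, default_cfg):
        cfg = dict(default_cfg)
        cfg["sleep"] = {**cfg["sleep"], "onset_jitter_sd_min": 0.0, "duration_jitter_sd_min": 0.0}
        day = wc.generate_day_streams(profile, 0, self._params(), seed=2, cfg=cfg)
        # 22:00-06:00 wrap window: steps identically zero, METs exactly 1.0
        asleep = np.zeros(MINUTES_PER_DAY, dtype=bool)
        asleep[22 * 60 :] = True
        asleep[: 6 * 60] = True
        assert day.steps[asleep].sum() == 0.0
        assert np.all(day.mets[asleep] == 1.0)

    def test_sleep_epochs_cover_windows(self, profile):
        day = wc.generate_day_streams(profile, 0, self._params(nap_probability=1.0), seed=3)
        # 30-s record: two epochs per in-bed minute; 60-s record: one per minute
        assert len(day.sleep30) == 2 * len(day.sleep60)
        minutes30 = np.unique(np.floor(day.sleep30["start_min"].to_numpy()))
        assert np.array_equal(minutes30, np.sort(day.sleep60["start_min"].to_numpy()))

    def test_calorie_conversion(self, profile):
        day = wc.generate_day_streams(profile, 0, self._params(), seed=4)
        np.testing.assert_allclose(day.calories, day.mets * 3.5 * profile.weight_kg / 200.0)

    def test_overlapping_windows_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            _window_mask([(1200, 120), (1300, 1350)])  # nap inside main wrap window

    def test_effect_map_shifts_latent_mesor_exactly(self, default_cfg):
        # same subject index and seed, diagnosis flipped: deterministic shift
        sd = default_cfg["rhythm"]["hr_mesor_sd"]
        spec = wc.CohortSpec(
            n_subjects=5, prevalence=0.5, n_days_per_subject=1, effect_map={"hr_mesor": 1.7 / sd}, seed=8
        )
        for i in range(5):
            base = wc.SubjectProfile(f"S{i}", "male", 144, 150, 47, "control")
            pos = replace(base, diagnosis="positive")
            d = (
                wc.generate_subject_params(pos, spec, i).hr_mesor
                - wc.generate_subject_params(base, spec, i).hr_mesor
            )
            assert d == pytest.approx(1.7, abs=1e-12)


class TestMissingness:
    def test_rate_zero_is_identity(self, small_cohort):
        _, _, days = small_cohort
        day = days[0]
        out = wc.inject_missingness(day, 0.0, seed=1)
        np.testing.assert_array_equal(out.hr, day.hr)
        np.testing.assert_array_equal(out.steps, day.steps)

    def test_rate_one_blanks_everything_and_invalidates_day(self, profile):
        day = wc.generate_day_streams(
            profile,
            0,
            wc.SubjectParams(80, 12, 14, 5, 0.5, 12, 14, 22, 8, 0.0, 45, 5),
            seed=1,
        )
        out = wc.inject_missingness(day, 1.0, seed=2)
        assert np.isnan(out.hr).all() and np.isnan(out.mets).all()
        assert not wc.compute_validity(out).day_valid

    def test_reproducible_mask(self, small_cohort):
        _, _, days = small_cohort
        a = wc.inject_missingness(days[0], 0.3, seed=7)
        b = wc.inject_missingness(days[0], 0.3, seed=7)
        np.testing.assert_array_equal(np.isnan(a.hr), np.isnan(b.hr))

    def test_no_data_fabricated(self, small_cohort):
        _, _, days = small_cohort
        out = wc.inject_missingness(days[0], 0.3, seed=7)
        keep = ~np.isnan(out.hr)
        np.testing.assert_array_equal(out.hr[keep], days[0].hr[keep])


class TestDatasetAndIO:
    def test_generate_dataset_determinism(self):
        spec = wc.CohortSpec(n_subjects=4, prevalence=0.5, n_days_per_subject=2, seed=21)
        p1, d1 = wc.generate_dataset(spec)
        p2, d2 = wc.generate_dataset(spec)
        assert p1 == p2
        for a, b in zip(d1, d2):
            np.testing.assert_array_equal(a.hr, b.hr)
            pd.testing.assert_frame_equal(a.sleep30, b.sleep30)

    def test_epoch_minute_conservation(self, small_cohort):
        # in-bed 30-s minutes + non-sleep minutes = 1440 within epoch rounding
        _, _, days = small_cohort
        for day in days[:6]:
            inbed_min = len(day.sleep30) * 0.5
            non_sleep = MINUTES_PER_DAY - len(day.sleep60)
            assert inbed_min + non_sleep == pytest.approx(MINUTES_PER_DAY, abs=0.5)

    def test_write_streams_csv_round_trip(self, tmp_path, small_cohort):
        _, profiles, days = small_cohort
        paths = wc.write_streams_csv(profiles[:2], days[:2], tmp_path)
        subjects = pd.read_csv(paths["subjects"])
        assert list(subjects["subject_id"]) == [p.subject_id for p in profiles[:2]]
        minutes = pd.read_csv(paths["minute_streams"])
        assert set(minutes["variable"]) == {"hr", "steps", "intensity", "mets", "calories"}
        # missing slots omitted, none fabricated
        hr0 = minutes[(minutes["variable"] == "hr") & (minutes["date_index"] == days[0].date_index) & (minutes["subject_id"] == days[0].subject_id)]
        assert len(hr0) == int((~np.isnan(days[0].hr)).sum())
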