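"""Validity rules, sleep windows, sleep/vitals summaries, BMR equations."""

import math

import numpy as np
import pandas as pd
import pytest

import wearcirc as wc
from wearcirc.synthetic import MINUTES_PER_DAY

from conftest import make_day, sleep30_frame


class TestValidity:
    def test_29_minutes_per_hour_invalidates_day(self):
        hr = np.full(MINUTES_PER_DAY, np.nan)
        for h in range(24):
            hr[h * 60 : h * 60 + 29] = 80.0  # one short of the rule
        v = wc.compute_validity(make_day(hr=hr))
        assert not v.hour_valid.any()
        assert not v.day_valid

    def test_exactly_30_minutes_in_exactly_5_hours_is_valid(self):
        # boundary inclusive: "less than 30" / "less than 5" read strictly
        hr = np.full(MINUTES_PER_DAY, np.nan)
        for h in range(5):
            hr[h * 60 : h * 60 + 30] = 80.0
        v = wc.compute_validity(make_day(hr=hr))
        assert v.hour_valid.sum() == 5
        assert v.day_valid

    def test_fully_worn_day_has_24_valid_hours(self):
        v = wc.compute_validity(make_day())
        assert v.hour_valid.sum() == 24 and v.day_valid

    def test_monotonicity_adding_wear_never_invalidates(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            worn = rng.random(MINUTES_PER_DAY) < rng.uniform(0.2, 0.8)
            hr = np.where(worn, 80.0, np.nan)
            v0 = wc.compute_validity(make_day(hr=hr))
            add = np.flatnonzero(~worn)
            hr2 = hr.copy()
            hr2[rng.choice(add, size=min(90, add.size), replace=False)] = 80.0
            v1 = wc.compute_validity(make_day(hr=hr2))
            assert v1.hour_valid.sum() >= v0.hour_valid.sum()
            assert v1.day_valid >= v0.day_valid


class TestSleepWindows:
    def test_single_nocturnal_block(self):
        s30 = sleep30_frame(22 * 60, ["light"] * (9 * 120))  # 9 h from 22:00, wraps
        w = wc.detect_sleep_windows(s30)
        assert w.has_main and len(w.naps) == 0
        assert w.main_onset_hour == pytest.approx(22.0)
        assert w.main_offset_hour == pytest.approx(7.0)

    def test_nap_detected_and_counted(self):
        night = sleep30_frame(22 * 60, ["light"] * 240)  # 2 h night block
        nap = sleep30_frame(14 * 60, ["light"] * 70 + ["wake"] * 10)  # 40 min nap
        s30 = pd.concat([night, nap], ignore_index=True).sort_values("start_min", ignore_index=True)
        w = wc.detect_sleep_windows(s30)
        assert len(w.naps) == 1
        summary = wc.summarize_sleep(s30, pd.DataFrame({"start_min": [], "state": []}), w)
        assert summary["sleep30_nap_inbed_min"] == pytest.approx(40.0)
        assert summary["sleep30_nap_asleep_min"] == pytest.approx(35.0)

    def test_equal_length_tie_breaks_to_earlier_block(self):
        b1 = sleep30_frame(21 * 60, ["light"] * 120)  # 21:00, 1 h
        b2 = sleep30_frame(23 * 60, ["light"] * 120)  # 23:00, 1 h
        s30 = pd.concat([b1, b2], ignore_index=True).sort_values("start_min", ignore_index=True)
        w = wc.detect_sleep_windows(s30)
        assert w.main_onset_hour == pytest.approx(21.0)

    def test_no_epochs_no_windows(self):
        s30 = pd.DataFrame({"start_min": pd.Series(dtype=float), "stage": pd.Series(dtype=str), "in_bed": pd.Series(dtype=bool)})
        w = wc.detect_sleep_windows(s30)
        assert not w.has_main and w.naps == [] and math.isnan(w.main_onset_hour)

    def test_short_fragment_is_not_a_nap(self):
        night = sleep30_frame(22 * 60, ["light"] * 240)
        frag = sleep30_frame(15 * 60, ["light"] * 10)  # 5 min < 10-min floor
        s30 = pd.concat([night, frag], ignore_index=True).sort_values("start_min", ignore_index=True)
        assert len(wc.detect_sleep_windows(s30).naps) == 0

    def test_bedtime_daytime_partition(self, small_cohort):
        _, _, days = small_cohort
        for day in days[:6]:
            w = wc.detect_sleep_windows(day.sleep30)
            assert w.bedtime_mask.sum() + (~w.bedtime_mask).sum() == MINUTES_PER_DAY


class TestSummarizeSleep:
    def test_toy_night_enumeration_oracle(self):
        # 10 epochs counted by hand: 2 wake, 4 light, 3 deep, 1 rem
        stages = ["wake", "light", "light", "deep", "rem", "deep", "light", "wake", "light", "deep"]
        s30 = sleep30_frame(22 * 60, stages)
        s60 = pd.DataFrame({"start_min": np.arange(1320, 1325), "state": ["asleep", "asleep", "restless", "asleep", "awake"]})
        out = wc.summarize_sleep(s30, s60)
        assert out["sleep30_inbed_min"] == pytest.approx(5.0)
        assert out["sleep30_asleep_min"] == pytest.approx(4.0)
        assert out["sleep30_deep_min"] == pytest.approx(1.5)
        assert out["sleep30_deep_epochs"] == 3
        assert out["sleep30_light_epochs"] == 4
        assert out["sleep30_rem_rate_pct"] == pytest.approx(100.0 * 1 / 8)
        assert out["sleep30_wake_rate_pct"] == pytest.approx(100.0 * 2 / 10)
        assert out["sleep30_quality_pct"] == pytest.approx(80.0)
        assert out["sleep60_asleep_min"] == 3.0
        assert out["sleep60_quality_pct"] == pytest.approx(100.0 * 3 / 5)

    def test_only_light_night_is_all_light(self):
        s30 = sleep30_frame(23 * 60, ["light"] * 100)
        out = wc.summarize_sleep(s30, pd.DataFrame({"start_min": [], "state": []}))
        assert out["sleep30_light_rate_pct"] == pytest.approx(100.0)
        assert out["sleep30_deep_rate_pct"] == 0.0 and out["sleep30_rem_rate_pct"] == 0.0

    def test_zero_inbed_time_reports_missing_not_zero(self):
        s30 = pd.DataFrame({"start_min": pd.Series(dtype=float), "stage": pd.Series(dtype=str), "in_bed": pd.Series(dtype=bool)})
        out = wc.summarize_sleep(s30, pd.DataFrame({"start_min": [], "state": []}))
        assert math.isnan(out["sleep30_quality_pct"])
        assert math.isnan(out["sleep60_quality_pct"])

    def test_stage_minutes_conserve_inbed_time(self, small_cohort):
        _, _, days = small_cohort
        for day in days[:8]:
            w = wc.detect_sleep_windows(day.sleep30)
            out = wc.summarize_sleep(day.sleep30, day.sleep60, w)
            if math.isnan(out["sleep30_inbed_min"]):
                continue
            total = sum(out[f"sleep30_{st}_min"] for st in ("deep", "light", "rem", "wake"))
            assert total == pytest.approx(out["sleep30_inbed_min"], abs=0.5)
            assert out["sleep30_deep_min"] + out["sleep30_light_min"] + out["sleep30_rem_min"] <= out["sleep30_asleep_min"] + 0.5


class TestBMR:
    def test_mifflin_hand_arithmetic(self):
        # male, 35 kg, 140 cm, 12.0 y: 10*35 + 6.25*140 - 5*12 + 5 = 1170
        assert wc.mifflin_st_jeor_bmr("male", 35.0, 140.0, 12.0) == pytest.approx(1170.0)

    def test_consumption_equal_to_bmr_gives_zero(self, profile):
        bmr = wc.harris_benedict_bmr("male", profile.weight_kg, profile.height_cm, profile.age_months / 12.0)
        out = wc.bmr_features(profile, bmr)
        assert out["cal_diff_harris_benedict"] == pytest.approx(0.0)

    def test_high_consumption_gives_negative_feature(self, profile):
        # consumption far above any child BMR estimate must be negative
        out = wc.bmr_features(profile, 2051.0)
        assert out["cal_diff_harris_benedict"] < 0
        assert out["cal_diff_mifflin_stjeor"] < 0
        hb = wc.harris_benedict_bmr("male", 47.0, 150.0, 12.0)
        assert out["cal_diff_harris_benedict"] == pytest.approx(hb - 2051.0)

    def test_katch_mcardle_uses_boer_lbm(self):
        lbm = wc.boer_lean_body_mass("female", 45.0, 150.0)
        assert wc.katch_mcardle_bmr("female", 45.0, 150.0) == pytest.approx(370.0 + 21.6 * lbm)

    def test_missing_calories_propagates_missing(self, profile):
        out = wc.bmr_features(profile, math.nan)
        assert all(math.isnan(v) for v in out.values())


class TestMetBins:
    def test_constant_one_met_day_is_all_sedentary(self):
        out = wc.met_activity_bins(np.full(MINUTES_PER_DAY, 1.0))
        assert out["met_sedentary_min"] == MINUTES_PER_DAY
        assert out["met_light_min"] == out["met_moderate_min"] == out["met_vigorous_min"] == 0

    def test_seven_met_hour_is_60_vigorous_minutes(self):
        mets = np.full(MINUTES_PER_DAY, np.nan)
        mets[600:660] = 7.0
        out = wc.met_activity_bins(mets)
        assert out["met_vigorous_min"] == 60.0
        assert sum(out.values()) == 60.0

    def test_mixed_toy_vector_hand_count(self):
        mets = np.array([1.0, 1.4, 1.5, 2.9, 3.0, 5.9, 6.0, 9.0, 1.2, 4.0])
        out = wc.met_activity_bins(mets)
        assert out == {
            "met_sedentary_min": 3.0,
            "met_light_min": 2.0,
            "met_moderate_min": 3.0,
            "met_vigorous_min": 2.0,
        }


class TestVitals:
    def test_block_order_and_bin_conservation(self, small_cohort):
        _, profiles, days = small_cohort
        by_id = {p.subject_id: p for p in profiles}
        for day in days[:8]:
            v = wc.compute_validity(day)
            if not v.day_valid:
                continue
            w = wc.detect_sleep_windows(day.sleep30)
            out = wc.summarize_vitals(day, w, v, by_id[day.subject_id])
            for prefix in ("hr", "hr_bed", "hr_day", "met", "intensity"):
                lo, mid, hi = out[f"{prefix}_min"], out[f"{prefix}_mean"], out[f"{prefix}_max"]
                if not math.isnan(mid):
                    assert lo <= mid <= hi
            bins = sum(out[k] for k in ("met_sedentary_min", "met_light_min", "met_moderate_min", "met_vigorous_min"))
            assert bins == int((v.worn & ~np.isnan(day.mets)).sum())
            assert out["steps_bed_sum"] + out["steps_day_sum"] == pytest.approx(out["steps_sum"])

    def test_invalid_day_yields_none(self, profile):
        assert wc.daily_summary(make_day(hr=None), profile) is None
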