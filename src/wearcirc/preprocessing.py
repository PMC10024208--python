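"""Wear-time validity filtering and per-day wearable summaries.

A minute of wear is "worn" when the device recorded a heart-rate sample for
it. An hour is valid with at least 30 worn minutes and a day is valid with
at least 5 valid hours (boundaries inclusive); invalid days are excluded
from all feature computation.

Sleep is summarized from the 30-s stage epochs (wake/light/deep/rem with an
in-bed flag) and the 60-s state epochs (asleep/restless/awake). Days are
treated as circular 24-h records, so a main sleep episode that wraps
midnight is one block. Daily vitals cover heart rate (bedtime/daytime/
overall), steps, intensity, METs with standard activity cutoffs, calorie
total, and the difference between three basal-metabolic-rate equations
(revised Harris-Benedict, Katch-McArdle with Boer lean body mass,
Mifflin-St Jeor) and the day's measured calorie consumption.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import load_defaults, PipelineConfig
from .synthetic import MINUTES_PER_DAY, DeviceDayStreams, SubjectProfile

__all__ = [
    "ValidityMask",
    "SleepWindows",
    "compute_validity",
    "detect_sleep_windows",
    "summarize_sleep",
    "sleep_quality_pct",
    "bmr_features",
    "harris_benedict_bmr",
    "mifflin_st_jeor_bmr",
    "katch_mcardle_bmr",
    "boer_lean_body_mass",
    "met_activity_bins",
    "summarize_vitals",
    "daily_summary",
]


# ---------------------------------------------------------------------------
# validity


@dataclass(frozen=True)
class ValidityMask:
    subject_id: str
    date_index: int
    hour_valid: np.ndarray  # 24 booleans
    day_valid: bool
    worn: np.ndarray  # 1440 booleans, minute-level wear


def compute_validity(
    streams: DeviceDayStreams,
    min_worn_minutes_per_hour: int = 30,
    min_valid_hours_per_day: int = 5,
) -> ValidityMask:
    """Hour valid iff >= 30 worn minutes; day valid iff >= 5 valid hours."""
    worn = ~np.isnan(streams.hr)
    per_hour = worn.reshape(24, 60).sum(axis=1)
    hour_valid = per_hour >= min_worn_minutes_per_hour
    return ValidityMask(
        subject_id=streams.subject_id,
        date_index=streams.date_index,
        hour_valid=hour_valid,
        day_valid=bool(hour_valid.sum() >= min_valid_hours_per_day),
        worn=worn,
    )


# ---------------------------------------------------------------------------
# sleep windows


@dataclass(frozen=True)
class SleepWindows:
    """Main sleep block and nap blocks, as epoch-index arrays into sleep30.

    ``main``/``naps`` index rows of the sleep30 table. ``bedtime_mask`` marks
    the 1440 minutes covered by any sleep window; daytime is its complement.
    ``main_onset_hour``/``main_offset_hour`` are clock hours in [0, 24).
    """

    main: np.ndarray
    naps: list[np.ndarray]
    bedtime_mask: np.ndarray
    main_onset_hour: float
    main_offset_hour: float

    @property
    def has_main(self) -> bool:
        return self.main.size > 0


def _circular_blocks(start_min: np.ndarray, epoch_len: float) -> list[np.ndarray]:
    """Group sorted epoch starts into contiguous blocks on a circular day."""
    if start_min.size == 0:
        return []
    order = np.argsort(start_min)
    t = start_min[order]
    breaks = np.flatnonzero(np.diff(t) > epoch_len + 1e-9)
    blocks = [order[s:e] for s, e in zip(np.r_[0, breaks + 1], np.r_[breaks + 1, t.size])]
    # merge a block ending at midnight with one starting at 00:00 (wrap)
    if len(blocks) > 1:
        first, last = blocks[0], blocks[-1]
        if t[0] <= epoch_len / 2 and t[-1] >= MINUTES_PER_DAY - epoch_len:
            blocks = [np.concatenate([last, first])] + blocks[1:-1]
    return blocks


def detect_sleep_windows(
    sleep30: pd.DataFrame,
    main_window_start_hour: float = 20.0,
    main_window_end_hour: float = 10.0,
    min_nap_minutes: float = 10.0,
) -> SleepWindows:
    """Split in-bed epochs into the main sleep episode and naps.

    Main sleep is the longest in-bed block with any epoch in the nocturnal
    window (20:00-10:00 by default); on ties the block with the earlier
    start minute wins. Every other block lasting at least ``min_nap_minutes``
    is a nap; shorter fragments are ignored.
    """
    in_bed = sleep30[sleep30["in_bed"]] if "in_bed" in sleep30 else sleep30
    starts = in_bed["start_min"].to_numpy(dtype=float)
    idx_map = in_bed.index.to_numpy()
    blocks = _circular_blocks(starts, epoch_len=0.5)

    def _nocturnal(block: np.ndarray) -> bool:
        hours = (starts[block] / 60.0) % 24.0
        return bool(np.any((hours >= main_window_start_hour) | (hours < main_window_end_hour)))

    candidates = [b for b in blocks if _nocturnal(b)]
    main = np.array([], dtype=int)
    if candidates:
        # longest block; tie-break on earlier start minute
        main = min(candidates, key=lambda b: (-b.size, float(starts[b].min())))
    naps = [
        b
        for b in blocks
        if b is not main and b.size * 0.5 >= min_nap_minutes
    ]

    mask = np.zeros(MINUTES_PER_DAY, dtype=bool)
    for b in [main] + naps:
        if b.size:
            mask[np.floor(starts[b]).astype(int) % MINUTES_PER_DAY] = True

    if main.size:
        onset = float(starts[main[0]]) / 60.0 % 24.0
        offset = (float(starts[main[-1]]) + 0.5) / 60.0 % 24.0
    else:
        onset = offset = math.nan
    return SleepWindows(
        main=idx_map[main] if main.size else main,
        naps=[idx_map[b] for b in naps],
        bedtime_mask=mask,
        main_onset_hour=onset,
        main_offset_hour=offset,
    )


# ---------------------------------------------------------------------------
# sleep summaries


def sleep_quality_pct(asleep: float, restless: float, awake: float) -> float:
    """Sleep quality as % of in-bed time spent asleep: 100*a/(a+r+w)."""
    denom = asleep + restless + awake
    return math.nan if denom <= 0 else 100.0 * asleep / denom


def summarize_sleep(
    sleep30: pd.DataFrame,
    sleep60: pd.DataFrame,
    windows: SleepWindows | None = None,
    cfg: dict | None = None,
) -> dict[str, float]:
    """Per-day sleep features from both epoch records.

    Durations are epoch counts times epoch length (minutes); the
    ``*_epochs`` features are the raw 30-s epoch counts of each stage over
    the main sleep. Stage rates are % of main-sleep asleep time except the
    wake rate, which is % of in-bed time; quality30 = asleep/in-bed and
    quality60 = asleep/(asleep+restless+awake), both as percentages and
    reported missing (never 0) when the denominator is empty.
    """
    if windows is None:
        det = (cfg or load_defaults())["sleep_detection"]
        windows = detect_sleep_windows(
            sleep30,
            det["main_window_start_hour"],
            det["main_window_end_hour"],
            det["min_nap_minutes"],
        )
    out: dict[str, float] = {}
    stages = sleep30["stage"]

    main = sleep30.loc[windows.main] if windows.has_main else sleep30.iloc[:0]
    n_inbed = len(main)
    counts = {st: int((main["stage"] == st).sum()) for st in ("wake", "light", "deep", "rem")}
    n_asleep = n_inbed - counts["wake"]

    out["sleep30_asleep_min"] = n_asleep * 0.5 if n_inbed else math.nan
    out["sleep30_inbed_min"] = n_inbed * 0.5 if n_inbed else math.nan
    for st in ("deep", "light", "rem", "wake"):
        out[f"sleep30_{st}_min"] = counts[st] * 0.5 if n_inbed else math.nan
        out[f"sleep30_{st}_epochs"] = float(counts[st]) if n_inbed else math.nan
    for st in ("deep", "light", "rem"):
        out[f"sleep30_{st}_rate_pct"] = 100.0 * counts[st] / n_asleep if n_asleep else math.nan
    out["sleep30_wake_rate_pct"] = 100.0 * counts["wake"] / n_inbed if n_inbed else math.nan
    out["sleep30_quality_pct"] = 100.0 * n_asleep / n_inbed if n_inbed else math.nan

    nap_idx = np.concatenate(windows.naps) if windows.naps else np.array([], dtype=int)
    naps = sleep30.loc[nap_idx]
    out["sleep30_nap_inbed_min"] = len(naps) * 0.5
    out["sleep30_nap_asleep_min"] = float((naps["stage"] != "wake").sum()) * 0.5

    n60 = {st: float((sleep60["state"] == st).sum()) for st in ("asleep", "restless", "awake")}
    total60 = sum(n60.values())
    out["sleep60_asleep_min"] = n60["asleep"] if total60 else math.nan
    out["sleep60_restless_min"] = n60["restless"] if total60 else math.nan
    out["sleep60_awake_min"] = n60["awake"] if total60 else math.nan
    out["sleep60_quality_pct"] = sleep_quality_pct(n60["asleep"], n60["restless"], n60["awake"])

    out["sleep_onset_hour"] = windows.main_onset_hour
    out["sleep_offset_hour"] = windows.main_offset_hour
    return out


# ---------------------------------------------------------------------------
# basal metabolic rate


def harris_benedict_bmr(sex: str, weight_kg: float, height_cm: float, age_years: float) -> float:
    """Revised Harris-Benedict (Roza & Shizgal) BMR in kcal/day."""
    if sex == "male":
        return 88.362 + 13.397 * weight_kg + 4.799 * height_cm - 5.677 * age_years
    return 447.593 + 9.247 * weight_kg + 3.098 * height_cm - 4.330 * age_years


def mifflin_st_jeor_bmr(sex: str, weight_kg: float, height_cm: float, age_years: float) -> float:
    """Mifflin-St Jeor BMR in kcal/day."""
    base = 10.0 * weight_kg + 6.25 * height_cm - 5.0 * age_years
    return base + (5.0 if sex == "male" else -161.0)


def boer_lean_body_mass(sex: str, weight_kg: float, height_cm: float) -> float:
    """Boer formula estimate of lean body mass in kg."""
    if sex == "male":
        return 0.407 * weight_kg + 0.267 * height_cm - 19.2
    return 0.252 * weight_kg + 0.473 * height_cm - 48.3


def katch_mcardle_bmr(sex: str, weight_kg: float, height_cm: float) -> float:
    """Katch-McArdle BMR from Boer lean body mass, kcal/day."""
    return 370.0 + 21.6 * boer_lean_body_mass(sex, weight_kg, height_cm)


def bmr_features(profile: SubjectProfile, sum_calories: float) -> dict[str, float]:
    """Three BMR-minus-consumption differences in kcal.

    Each feature is equation_BMR - measured daily calories, so a day whose
    consumption exceeds the estimated BMR yields a negative value.
    """
    if math.isnan(sum_calories):
        return {k: math.nan for k in ("cal_diff_harris_benedict", "cal_diff_katch_mcardle", "cal_diff_mifflin_stjeor")}
    age_y = profile.age_months / 12.0
    return {
        "cal_diff_harris_benedict": harris_benedict_bmr(profile.sex, profile.weight_kg, profile.height_cm, age_y)
        - sum_calories,
        "cal_diff_katch_mcardle": katch_mcardle_bmr(profile.sex, profile.weight_kg, profile.height_cm) - sum_calories,
        "cal_diff_mifflin_stjeor": mifflin_st_jeor_bmr(profile.sex, profile.weight_kg, profile.height_cm, age_y)
        - sum_calories,
    }


# ---------------------------------------------------------------------------
# activity and vitals


def met_activity_bins(
    mets: np.ndarray,
    worn: np.ndarray | None = None,
    cutoffs: dict[str, float] | None = None,
) -> dict[str, float]:
    """Minutes of sedentary/light/moderate/vigorous activity over worn time.

    Default cutoffs: sedentary < 1.5, light [1.5, 3), moderate [3, 6),
    vigorous >= 6 METs.
    """
    cuts = cutoffs or load_defaults()["met_cutoffs"]
    valid = ~np.isnan(mets) if worn is None else (worn & ~np.isnan(mets))
    x = mets[valid]
    return {
        "met_sedentary_min": float(np.sum(x < cuts["light"])),
        "met_light_min": float(np.sum((x >= cuts["light"]) & (x < cuts["moderate"]))),
        "met_moderate_min": float(np.sum((x >= cuts["moderate"]) & (x < cuts["vigorous"]))),
        "met_vigorous_min": float(np.sum(x >= cuts["vigorous"])),
    }


def _block_stats(x: np.ndarray, mask: np.ndarray, prefix: str) -> dict[str, float]:
    vals = x[mask & ~np.isnan(x)]
    if vals.size == 0:
        return {f"{prefix}_max": math.nan, f"{prefix}_min": math.nan, f"{prefix}_mean": math.nan}
    return {
        f"{prefix}_max": float(vals.max()),
        f"{prefix}_min": float(vals.min()),
        f"{prefix}_mean": float(vals.mean()),
    }


def summarize_vitals(
    streams: DeviceDayStreams,
    windows: SleepWindows,
    validity: ValidityMask,
    profile: SubjectProfile,
    cfg: dict | None = None,
) -> dict[str, float]:
    """Heart rate, steps, intensity, MET and calorie features for one day.

    Bedtime is the union of detected sleep windows, daytime its complement;
    only worn minutes contribute. Calorie features require at least the
    valid-day level of wear to be meaningful and use the worn-minute sum.
    """
    tree = cfg or load_defaults()
    worn = validity.worn
    bed = windows.bedtime_mask
    out: dict[str, float] = {}

    hr = streams.hr
    out.update(_block_stats(hr, worn & bed, "hr_bed"))
    out.update(_block_stats(hr, worn & ~bed, "hr_day"))
    out.update(_block_stats(hr, worn, "hr"))
    hr_worn = hr[worn & ~np.isnan(hr)]
    out["hr_var"] = float(np.var(hr_worn, ddof=1)) if hr_worn.size > 1 else math.nan
    out["hr_sd"] = math.sqrt(out["hr_var"]) if not math.isnan(out["hr_var"]) else math.nan

    steps = streams.steps
    steps_worn = np.where(worn, steps, np.nan)
    out["steps_bed_sum"] = float(np.nansum(steps_worn[bed])) if np.any(worn & bed) else math.nan
    out["steps_day_sum"] = float(np.nansum(steps_worn[~bed])) if np.any(worn & ~bed) else math.nan
    out["steps_sum"] = float(np.nansum(steps_worn)) if np.any(worn) else math.nan

    out.update(_block_stats(streams.intensity, worn, "intensity"))
    out.update(_block_stats(streams.mets, worn, "met"))
    out.update(met_activity_bins(streams.mets, worn, tree["met_cutoffs"]))

    out["cal_sum"] = float(np.nansum(np.where(worn, streams.calories, np.nan))) if np.any(worn) else math.nan
    out.update(bmr_features(profile, out["cal_sum"]))
    return out


def daily_summary(
    streams: DeviceDayStreams,
    profile: SubjectProfile,
    cfg: PipelineConfig | dict | None = None,
) -> dict[str, float] | None:
    """All non-cosinor features for one subject-day, or None if invalid.

    Applies the wear-validity rule first; invalid days yield None and are
    excluded from the training data entirely.
    """
    tree = cfg.to_dict() if isinstance(cfg, PipelineConfig) else (cfg or load_defaults())
    v = tree["validity"]
    validity = compute_validity(streams, v["min_worn_minutes_per_hour"], v["min_valid_hours_per_day"])
    if not validity.day_valid:
        return None
    det = tree["sleep_detection"]
    windows = detect_sleep_windows(
        streams.sleep30,
        det["main_window_start_hour"],
        det["main_window_end_hour"],
        det["min_nap_minutes"],
    )
    out = {"subject_id": streams.subject_id, "date_index": streams.date_index}
    out.update(summarize_sleep(streams.sleep30, streams.sleep60, windows))
    out.update(summarize_vitals(streams, windows, validity, profile, tree))
    return out
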