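"""Assembly of per-day training entries: 64 circadian features + sex + label.

One training entry is one valid subject-day. The feature registry fixes the
names and order of the 64 circadian features; entries are linked to the
subject-level diagnosis through the unique subject identifier. Missing
values are kept as NaN and flagged, never imputed here.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
import json
import logging

import numpy as np
import pandas as pd

from .circadian import fit_cosinor, hourly_bins, nonparam_metrics, CosinorError
from .config import PipelineConfig, load_defaults
from .preprocessing import daily_summary
from .synthetic import DeviceDayStreams, SubjectProfile

__all__ = [
    "FEATURE_REGISTRY",
    "DISPLAY_NAMES",
    "TrainingDataset",
    "extract_day_features",
    "assemble_entries",
    "class_proportion",
]

logger = logging.getLogger(__name__)

# Fixed order: sleep (30-s then 60-s records), calories, heart rate,
# intensity, METs, steps with rhythm metrics, then sleep timing.
FEATURE_REGISTRY: tuple[str, ...] = (
    # 30-s sleep record
    "sleep30_asleep_min",
    "sleep30_inbed_min",
    "sleep30_deep_min",
    "sleep30_light_min",
    "sleep30_rem_min",
    "sleep30_wake_min",
    "sleep30_nap_asleep_min",
    "sleep30_nap_inbed_min",
    "sleep30_deep_rate_pct",
    "sleep30_light_rate_pct",
    "sleep30_rem_rate_pct",
    "sleep30_wake_rate_pct",
    "sleep30_deep_epochs",
    "sleep30_light_epochs",
    "sleep30_rem_epochs",
    "sleep30_wake_epochs",
    "sleep30_quality_pct",
    # 60-s sleep record
    "sleep60_asleep_min",
    "sleep60_restless_min",
    "sleep60_awake_min",
    "sleep60_quality_pct",
    # calories
    "cal_diff_harris_benedict",
    "cal_diff_katch_mcardle",
    "cal_diff_mifflin_stjeor",
    "cal_sum",
    # heart rate
    "hr_acrophase",
    "hr_amplitude",
    "hr_mesor",
    "hr_gof_pct",
    "hr_bed_max",
    "hr_bed_min",
    "hr_bed_mean",
    "hr_day_max",
    "hr_day_min",
    "hr_day_mean",
    "hr_max",
    "hr_min",
    "hr_mean",
    "hr_var",
    "hr_sd",
    # intensity
    "intensity_max",
    "intensity_min",
    "intensity_mean",
    # METs
    "met_max",
    "met_min",
    "met_mean",
    "met_light_min",
    "met_moderate_min",
    "met_sedentary_min",
    "met_vigorous_min",
    # steps and rest-activity rhythm
    "steps_acrophase",
    "steps_amplitude",
    "steps_mesor",
    "steps_gof_pct",
    "steps_bed_sum",
    "steps_day_sum",
    "steps_sum",
    "steps_is",
    "steps_iv",
    "steps_l5",
    "steps_m10",
    "steps_ra",
    # sleep timing
    "sleep_onset_hour",
    "sleep_offset_hour",
)

assert len(FEATURE_REGISTRY) == 64

DISPLAY_NAMES: dict[str, str] = {
    "sleep30_asleep_min": "Duration of being asleep (30 s), min",
    "sleep30_inbed_min": "Duration of in-bed sleep (30 s), min",
    "sleep30_deep_min": "Duration of deep sleep, min",
    "sleep30_light_min": "Duration of light sleep, min",
    "sleep30_rem_min": "Duration of REM sleep, min",
    "sleep30_wake_min": "Duration of waking for short periods, min",
    "sleep30_nap_asleep_min": "Duration of being asleep during a nap, min",
    "sleep30_nap_inbed_min": "Duration of being in bed during a nap, min",
    "sleep30_deep_rate_pct": "Rate of deep sleep, %",
    "sleep30_light_rate_pct": "Rate of light sleep, %",
    "sleep30_rem_rate_pct": "Rate of REM sleep, %",
    "sleep30_wake_rate_pct": "Rate of wake, %",
    "sleep30_deep_epochs": "Duration of deep sleep stage (epochs)",
    "sleep30_light_epochs": "Duration of light sleep stage (epochs)",
    "sleep30_rem_epochs": "Duration of REM sleep stage (epochs)",
    "sleep30_wake_epochs": "Duration of being wake stage (epochs)",
    "sleep30_quality_pct": "Quality of sleep (30 s), %",
    "sleep60_asleep_min": "Duration of being asleep (60 s), min",
    "sleep60_restless_min": "Duration of restlessness, min",
    "sleep60_awake_min": "Duration of being wake (60 s), min",
    "sleep60_quality_pct": "Quality of sleep (60 s), %",
    "cal_diff_harris_benedict": "Difference between Harris-Benedict and BMR, kcal",
    "cal_diff_katch_mcardle": "Difference between Katch-McArdle and BMR, kcal",
    "cal_diff_mifflin_stjeor": "Difference between Mifflin-St Jeor and BMR, kcal",
    "cal_sum": "Sum of calories, kcal",
    "hr_acrophase": "Acrophase (heart rate), h",
    "hr_amplitude": "Amplitude (heart rate), bpm",
    "hr_mesor": "MESOR (heart rate), bpm",
    "hr_gof_pct": "Goodness of fit (heart rate), %",
    "hr_bed_max": "Bedtime maximum heart rate, bpm",
    "hr_bed_min": "Bedtime minimum heart rate, bpm",
    "hr_bed_mean": "Bedtime mean heart rate, bpm",
    "hr_day_max": "Daytime maximum heart rate, bpm",
    "hr_day_min": "Daytime minimum heart rate, bpm",
    "hr_day_mean": "Daytime mean heart rate, bpm",
    "hr_max": "Maximum heart rate, bpm",
    "hr_min": "Minimum heart rate, bpm",
    "hr_mean": "Mean heart rate, bpm",
    "hr_var": "Heart rate variance",
    "hr_sd": "Heart rate standard deviation, bpm",
    "intensity_max": "Intensity maximum",
    "intensity_min": "Intensity minimum",
    "intensity_mean": "Intensity mean",
    "met_max": "MET maximum",
    "met_min": "MET minimum",
    "met_mean": "MET average",
    "met_light_min": "Duration of light activity, min",
    "met_moderate_min": "Duration of moderate activity, min",
    "met_sedentary_min": "Duration of sedentary activity, min",
    "met_vigorous_min": "Duration of vigorous activity, min",
    "steps_acrophase": "Acrophase (steps), h",
    "steps_amplitude": "Amplitude (steps), steps/h",
    "steps_mesor": "MESOR (steps), steps/h",
    "steps_gof_pct": "Goodness of fit (steps), %",
    "steps_bed_sum": "Sum of bedtime steps",
    "steps_day_sum": "Sum of daytime steps",
    "steps_sum": "Sum of steps",
    "steps_is": "IS, 0-2",
    "steps_iv": "IV",
    "steps_l5": "L5 (steps/h)",
    "steps_m10": "M10 (steps/h)",
    "steps_ra": "RA, 0-1",
    "sleep_onset_hour": "Main sleep onset, h",
    "sleep_offset_hour": "Main sleep offset, h",
}


@dataclass
class TrainingDataset:
    """Per-day entries plus class counts; ``frame`` columns are subject_id,
    date_index, the 64 registry features in order, sex (0=female, 1=male)
    and label (0=control, 1=positive)."""

    frame: pd.DataFrame

    @property
    def positives(self) -> int:
        return int((self.frame["label"] == 1).sum())

    @property
    def controls(self) -> int:
        return int((self.frame["label"] == 0).sum())

    def __len__(self) -> int:
        return len(self.frame)


def extract_day_features(
    streams: DeviceDayStreams,
    profile: SubjectProfile,
    cfg: dict | PipelineConfig | None = None,
) -> dict[str, float] | None:
    """Full per-day feature dict (summaries + cosinor), or None if invalid.

    Heart-rate cosinor is fitted on worn per-minute samples; the steps
    rhythm (cosinor, L5/M10/RA) is computed on hourly step totals. IS/IV
    need several days and are filled in at assembly time from the subject's
    pooled record.
    """
    tree = cfg.to_dict() if isinstance(cfg, PipelineConfig) else (cfg or load_defaults())
    base = daily_summary(streams, profile, tree)
    if base is None:
        return None

    t_min = (np.arange(streams.hr.size) + 0.5) / 60.0
    try:
        hr_fit = fit_cosinor(t_min, streams.hr)
        base.update(
            hr_acrophase=hr_fit.acrophase,
            hr_amplitude=hr_fit.amplitude,
            hr_mesor=hr_fit.mesor,
            hr_gof_pct=hr_fit.gof,
        )
    except CosinorError:
        base.update(hr_acrophase=np.nan, hr_amplitude=np.nan, hr_mesor=np.nan, hr_gof_pct=np.nan)

    worn = ~np.isnan(streams.hr)
    steps_hourly = hourly_bins(np.where(worn, streams.steps, np.nan), how="sum")
    hours = np.arange(24) + 0.5
    try:
        st_fit = fit_cosinor(hours[~np.isnan(steps_hourly)], steps_hourly[~np.isnan(steps_hourly)])
        base.update(
            steps_acrophase=st_fit.acrophase,
            steps_amplitude=st_fit.amplitude,
            steps_mesor=st_fit.mesor,
            steps_gof_pct=st_fit.gof,
        )
    except CosinorError:
        base.update(steps_acrophase=np.nan, steps_amplitude=np.nan, steps_mesor=np.nan, steps_gof_pct=np.nan)

    base["_steps_hourly"] = steps_hourly  # consumed (and removed) at assembly
    return base


def assemble_entries(
    day_streams: list[DeviceDayStreams],
    profiles: list[SubjectProfile],
    cfg: dict | PipelineConfig | None = None,
) -> TrainingDataset:
    """Build the training table: one entry per valid subject-day.

    Invalid days are dropped; wearable days whose subject identifier has no
    profile are dropped with a logged warning count. Per-day L5/M10/RA come
    from that day's hourly steps; IS/IV are computed once per subject on
    the pooled hourly record over the subject's valid days and broadcast to
    each of their entries.
    """
    tree = cfg.to_dict() if isinstance(cfg, PipelineConfig) else (cfg or load_defaults())
    by_id = {p.subject_id: p for p in profiles}
    if len(by_id) != len(profiles):
        raise ValueError("subject_id values must be unique within the cohort")
    max_miss = tree["circadian"]["l5_m10_max_missing_frac"]

    rows: list[dict] = []
    hourly_by_subject: dict[str, list[np.ndarray]] = {}
    n_unmatched = 0
    for streams in day_streams:
        profile = by_id.get(streams.subject_id)
        if profile is None:
            n_unmatched += 1
            continue
        feats = extract_day_features(streams, profile, tree)
        if feats is None:
            continue
        steps_hourly = feats.pop("_steps_hourly")
        day_np = _day_nonparam(steps_hourly, max_miss)
        feats.update(day_np)
        hourly_by_subject.setdefault(streams.subject_id, []).append(steps_hourly)
        rows.append(feats)
    if n_unmatched:
        logger.warning("dropped %d wearable day(s) with no matching subject profile", n_unmatched)

    frame = pd.DataFrame(rows)
    if len(frame) == 0:
        frame = pd.DataFrame(columns=["subject_id", "date_index", *FEATURE_REGISTRY, "sex", "label"])
        return TrainingDataset(frame)

    # pooled multi-day IS/IV per subject, broadcast to that subject's entries
    is_iv: dict[str, tuple[float, float]] = {}
    for sid, days in hourly_by_subject.items():
        stacked = np.vstack(days)
        try:
            np_metrics = nonparam_metrics(stacked, max_missing_frac=max_miss)
            is_iv[sid] = (np_metrics.is_stat, np_metrics.iv_stat)
        except ValueError:
            is_iv[sid] = (np.nan, np.nan)
    frame["steps_is"] = frame["subject_id"].map(lambda s: is_iv[s][0])
    frame["steps_iv"] = frame["subject_id"].map(lambda s: is_iv[s][1])

    frame["sex"] = frame["subject_id"].map(lambda s: 1.0 if by_id[s].sex == "male" else 0.0)
    frame["label"] = frame["subject_id"].map(lambda s: 1 if by_id[s].diagnosis == "positive" else 0)
    frame = frame[["subject_id", "date_index", *FEATURE_REGISTRY, "sex", "label"]]
    return TrainingDataset(frame.reset_index(drop=True))


def _day_nonparam(steps_hourly: np.ndarray, max_missing_frac: float) -> dict[str, float]:
    from .circadian import extreme_window_mean

    l5 = extreme_window_mean(steps_hourly, 5, minimize=True, max_missing_frac=max_missing_frac)
    m10 = extreme_window_mean(steps_hourly, 10, minimize=False, max_missing_frac=max_missing_frac)
    denom = m10 + l5
    ra = (m10 - l5) / denom if denom and not np.isnan(denom) and denom > 0 else np.nan
    return {"steps_l5": l5, "steps_m10": m10, "steps_ra": ra, "steps_is": np.nan, "steps_iv": np.nan}


def class_proportion(dataset: TrainingDataset | pd.DataFrame) -> Fraction:
    """Positive-class fraction as an exact rational (display rounding last)."""
    frame = dataset.frame if isinstance(dataset, TrainingDataset) else dataset
    if len(frame) == 0:
        raise ValueError("empty dataset has no class proportion")
    return Fraction(int((frame["label"] == 1).sum()), len(frame))


def write_training_table(dataset: TrainingDataset, out_dir: str | Path) -> tuple[Path, Path]:
    """Write the assembled table as CSV plus a JSON schema sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    csv_path = out / "training_table.csv"
    schema_path = out / "training_table.schema.json"
    dataset.frame.to_csv(csv_path, index=False)
    schema = {
        "features": list(FEATURE_REGISTRY),
        "display_names": DISPLAY_NAMES,
        "extra_columns": ["subject_id", "date_index", "sex", "label"],
        "sex_encoding": {"male": 1, "female": 0},
        "label_encoding": {"positive": 1, "control": 0},
        "missing": "empty cell (NaN); never imputed at assembly",
    }
    schema_path.write_text(json.dumps(schema, indent=2))
    return csv_path, schema_path
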