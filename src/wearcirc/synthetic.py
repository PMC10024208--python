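"""Synthetic child-wearable cohort generator.

Emulates the statistical structure of per-minute wearable streams from a
consumer wrist tracker worn by 9-12 year olds: a 24-h sinusoidal heart-rate
rhythm with AR(1) noise, near-zero nocturnal steps with a cosine daytime
envelope, MET activity bouts, a consolidated main sleep episode plus
occasional afternoon naps scored as 30-s stage epochs and 60-s
asleep/restless/awake epochs, and hour-level non-wear gaps.

Each generated day is a self-contained circular 24-h record: the main sleep
episode appears as late-evening plus early-morning in-bed epochs of the same
date. The generator is fully deterministic given (spec, seed): the heart-rate
model is

    HR(t) = M + A * cos(2*pi*(t - phi)/24) + AR(1) noise

so the cosinor stage has recoverable ground truth, and positive subjects'
latent parameters are shifted by the configured standardized effect map.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .config import PipelineConfig, load_defaults

__all__ = [
    "CohortSpec",
    "SubjectProfile",
    "SubjectParams",
    "DeviceDayStreams",
    "generate_cohort",
    "generate_subject_params",
    "generate_day_streams",
    "inject_missingness",
    "generate_dataset",
    "write_streams_csv",
]

MINUTES_PER_DAY = 1440
SLEEP_STAGES = ("wake", "light", "deep", "rem")
SLEEP60_STATES = ("asleep", "restless", "awake")


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class CohortSpec:
    """What cohort to simulate: size, class prevalence, wear length, effects."""

    n_subjects: int
    prevalence: float
    n_days_per_subject: int = 21
    effect_map: dict[str, float] = field(default_factory=dict)
    missing_hour_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError(f"prevalence must be in [0, 1], got {self.prevalence}")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.n_days_per_subject < 1:
            raise ValueError("n_days_per_subject must be >= 1")
        if not 0.0 <= self.missing_hour_rate <= 1.0:
            raise ValueError("missing_hour_rate must be in [0, 1]")

    @classmethod
    def from_config(cls, cfg: PipelineConfig | dict) -> "CohortSpec":
        tree = cfg.to_dict() if isinstance(cfg, PipelineConfig) else cfg
        c = tree["cohort"]
        return cls(
            n_subjects=c["n_subjects"],
            prevalence=c["prevalence"],
            n_days_per_subject=c["n_days_per_subject"],
            effect_map=dict(c["effect_map"]),
            missing_hour_rate=c["missing_hour_rate"],
            seed=c["seed"],
        )


@dataclass(frozen=True)
class SubjectProfile:
    subject_id: str
    sex: str  # "male" | "female"
    age_months: float
    height_cm: float
    weight_kg: float
    diagnosis: str  # "positive" | "control"

    def __post_init__(self) -> None:
        if min(self.age_months, self.height_cm, self.weight_kg) <= 0:
            raise ValueError("anthropometrics must be positive")
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be male/female, got {self.sex!r}")
        if self.diagnosis not in ("positive", "control"):
            raise ValueError(f"diagnosis must be positive/control, got {self.diagnosis!r}")


@dataclass(frozen=True)
class SubjectParams:
    """Latent per-subject rhythm parameters (the generator's ground truth)."""

    hr_mesor: float
    hr_amplitude: float
    hr_acrophase: float  # hours in [0, 24)
    hr_noise_sd: float
    hr_ar1: float
    steps_level: float  # expected steps per awake minute at envelope centre
    steps_acrophase: float
    sleep_onset_hour: float
    sleep_duration_hour: float
    nap_probability: float
    nap_duration_median_min: float
    activity_bout_rate: float

    def __post_init__(self) -> None:
        if self.hr_mesor <= 0 or self.hr_amplitude < 0 or self.hr_noise_sd < 0:
            raise ValueError("invalid rhythm parameters")
        if not 0.0 <= self.hr_acrophase < 24.0:
            raise ValueError("acrophase must be in [0, 24)")


@dataclass
class DeviceDayStreams:
    """One subject-day of raw device output.

    Per-minute arrays have 1440 slots indexed by minute-of-day; missing
    (non-worn) slots are NaN, never silently zero. ``sleep30`` holds only
    in-bed 30-s epochs (epoch start in minutes, stage label); ``sleep60``
    holds 60-s epochs over the same windows.
    """

    subject_id: str
    date_index: int
    hr: np.ndarray
    steps: np.ndarray
    intensity: np.ndarray
    mets: np.ndarray
    calories: np.ndarray
    sleep30: pd.DataFrame  # columns: start_min (float, step 0.5), stage, in_bed
    sleep60: pd.DataFrame  # columns: start_min (int), state

    def validate(self) -> None:
        for name in ("hr", "steps", "intensity", "mets", "calories"):
            arr = getattr(self, name)
            if arr.shape != (MINUTES_PER_DAY,):
                raise ValueError(f"{name} must have {MINUTES_PER_DAY} slots")
        worn = ~np.isnan(self.mets)
        if np.any(self.mets[worn] < 1.0 - 1e-9):
            raise ValueError("METs must be >= 1.0 where present")
        for frame, col in ((self.sleep30, "start_min"), (self.sleep60, "start_min")):
            t = frame[col].to_numpy()
            if len(t) > 1 and np.any(np.diff(t) <= 0):
                raise ValueError("epoch times must be strictly increasing")

    def copy(self) -> "DeviceDayStreams":
        return DeviceDayStreams(
            self.subject_id,
            self.date_index,
            self.hr.copy(),
            self.steps.copy(),
            self.intensity.copy(),
            self.mets.copy(),
            self.calories.copy(),
            self.sleep30.copy(),
            self.sleep60.copy(),
        )


# ---------------------------------------------------------------------------
# cohort-level generation


def _subject_seed(spec_seed: int, subject_index: int, day: int = -1) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([spec_seed, subject_index, day + 1]))


def generate_cohort(spec: CohortSpec, cfg: PipelineConfig | dict | None = None) -> list[SubjectProfile]:
    """Draw subject profiles: sex, anthropometrics and diagnosis label.

    Anthropometrics target the 9-12 year old range of a two-year study visit
    (age ~144 months); the diagnosis is i.i.d. Bernoulli(prevalence).
    """
    pop = _section(cfg, "population")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xC0F0]))
    profiles: list[SubjectProfile] = []
    for i in range(spec.n_subjects):
        dx = "positive" if rng.random() < spec.prevalence else "control"
        male_frac = pop["male_fraction_positive"] if dx == "positive" else pop["male_fraction"]
        sex = "male" if rng.random() < male_frac else "female"
        age = max(108.0, rng.normal(pop["age_months_mean"], pop["age_months_sd"]))
        height = max(120.0, rng.normal(pop["height_cm_mean"], pop["height_cm_sd"]))
        weight = max(pop["weight_kg_min"], rng.normal(pop["weight_kg_mean"], pop["weight_kg_sd"]))
        profiles.append(
            SubjectProfile(
                subject_id=f"S{i:05d}",
                sex=sex,
                age_months=float(age),
                height_cm=float(height),
                weight_kg=float(weight),
                diagnosis=dx,
            )
        )
    return profiles


# effect-map family -> (latent parameter, between-subject SD source key)
_EFFECT_TARGETS = {
    "hr_mesor": ("hr_mesor", ("rhythm", "hr_mesor_sd")),
    "sleep_duration": ("sleep_duration_hour", ("sleep", "duration_hour_sd")),
    "steps_level": ("steps_level", ("rhythm", "steps_level_sd")),
    "activity_moderate": ("activity_bout_rate", None),  # SD = sqrt(rate), Poisson-like
    "nap_duration": ("nap_duration_median_min", None),  # SD = 0.3 * median
}


def generate_subject_params(
    profile: SubjectProfile,
    spec: CohortSpec,
    subject_index: int,
    cfg: PipelineConfig | dict | None = None,
) -> SubjectParams:
    """Draw latent rhythm parameters; positives get the effect-map shifts.

    Shifts are standardized: ``effect_map[family]`` is applied in units of
    the between-subject SD of the targeted latent parameter.
    """
    tree = _tree(cfg)
    r, s, a = tree["rhythm"], tree["sleep"], tree["activity"]
    rng = _subject_seed(spec.seed, subject_index)
    params = dict(
        hr_mesor=rng.normal(r["hr_mesor_mean"], r["hr_mesor_sd"]),
        hr_amplitude=max(1.0, rng.normal(r["hr_amplitude_mean"], r["hr_amplitude_sd"])),
        hr_acrophase=rng.normal(r["hr_acrophase_mean"], r["hr_acrophase_sd"]) % 24.0,
        hr_noise_sd=r["hr_noise_sd"],
        hr_ar1=r["hr_ar1"],
        steps_level=max(r["steps_level_min"], rng.normal(r["steps_level_mean"], r["steps_level_sd"])),
        steps_acrophase=rng.normal(r["steps_acrophase_mean"], r["steps_acrophase_sd"]) % 24.0,
        sleep_onset_hour=rng.normal(s["onset_hour_mean"], s["onset_hour_sd"]) % 24.0,
        sleep_duration_hour=max(5.0, rng.normal(s["duration_hour_mean"], s["duration_hour_sd"])),
        nap_probability=s["nap_probability"],
        nap_duration_median_min=s["nap_duration_median_min"],
        activity_bout_rate=a["bout_rate_per_day"],
    )
    if profile.diagnosis == "positive":
        for family, shift in spec.effect_map.items():
            if family not in _EFFECT_TARGETS:
                raise KeyError(f"unknown effect family: {family!r}")
            target, sd_key = _EFFECT_TARGETS[family]
            if sd_key is not None:
                sd = tree[sd_key[0]][sd_key[1]]
            elif family == "activity_moderate":
                sd = np.sqrt(a["bout_rate_per_day"])
            else:
                sd = 0.3 * s["nap_duration_median_min"]
            params[target] += shift * sd
        params["sleep_duration_hour"] = max(5.0, params["sleep_duration_hour"])
        params["steps_level"] = max(tree["rhythm"]["steps_level_min"], params["steps_level"])
        params["activity_bout_rate"] = max(0.0, params["activity_bout_rate"])
    return SubjectParams(**params)


# ---------------------------------------------------------------------------
# day-level generation


def _sleep_windows_for_day(params: SubjectParams, rng: np.random.Generator, s: dict) -> list[tuple[int, int]]:
    """Return sleep windows as (start_min, end_min) on a circular day.

    The main window wraps midnight (start in the evening, end next morning,
    both expressed on [0, 1440) with end < start meaning wrap). Windows are
    returned unwrapped as minute sets later; overlap is rejected.
    """
    onset = (params.sleep_onset_hour * 60.0 + rng.normal(0.0, s["onset_jitter_sd_min"])) % MINUTES_PER_DAY
    dur = max(240.0, params.sleep_duration_hour * 60.0 + rng.normal(0.0, s["duration_jitter_sd_min"]))
    dur = min(dur, 720.0)
    windows = [(int(round(onset)) % MINUTES_PER_DAY, int(round(onset + dur)) % MINUTES_PER_DAY)]
    if rng.random() < params.nap_probability:
        start_h = rng.uniform(s["nap_start_earliest_hour"], s["nap_start_latest_hour"])
        nap_dur = params.nap_duration_median_min * np.exp(rng.normal(0.0, s["nap_duration_sigma"]))
        nap_dur = float(np.clip(nap_dur, 10.0, 180.0))
        start = int(round(start_h * 60.0))
        windows.append((start, min(start + int(round(nap_dur)), MINUTES_PER_DAY)))
    return windows


def _window_mask(windows: Sequence[tuple[int, int]]) -> np.ndarray:
    """Boolean minute mask of the union of circular windows; rejects overlap."""
    mask = np.zeros(MINUTES_PER_DAY, dtype=bool)
    for start, end in windows:
        if start == end:
            continue
        idx = np.arange(start, end if end > start else end + MINUTES_PER_DAY) % MINUTES_PER_DAY
        if mask[idx].any():
            raise ValueError("overlapping sleep windows")
        mask[idx] = True
    return mask


def _sample_stage_runs(n_epochs: int, rng: np.random.Generator, s: dict) -> np.ndarray:
    """Semi-Markov stage sequence: geometric runs of wake/light/deep/rem."""
    stages: list[str] = []
    p_run = 1.0 / s["stage_mean_run_epochs"]
    probs = s["stage_probs"]
    asleep_stages = list(probs)
    asleep_p = np.array([probs[k] for k in asleep_stages], dtype=float)
    asleep_p /= asleep_p.sum()
    while len(stages) < n_epochs:
        if rng.random() < s["wake_epoch_prob"]:
            stage = "wake"
            run = 1 + rng.geometric(min(max(p_run * 4, 1e-6), 1.0))  # wake runs are short
        else:
            stage = str(rng.choice(asleep_stages, p=asleep_p))
            run = 1 + rng.geometric(p_run)
        stages.extend([stage] * int(run))
    return np.array(stages[:n_epochs])


def generate_day_streams(
    profile: SubjectProfile,
    day: int,
    params: SubjectParams,
    seed: int | None = None,
    cfg: PipelineConfig | dict | None = None,
    rng: np.random.Generator | None = None,
) -> DeviceDayStreams:
    """Simulate one fully worn subject-day (no missingness yet).

    Heart rate follows the cosine-plus-AR(1) model; steps are zero within
    sleep and zero-inflated negative binomial outside it with a cosine
    envelope; METs are a sedentary baseline plus activity bouts; calories
    are METs * 3.5 * weight / 200 kcal per minute (standard conversion).
    """
    tree = _tree(cfg)
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([0 if seed is None else seed, day]))
    r, s, a = tree["rhythm"], tree["sleep"], tree["activity"]

    t_hour = (np.arange(MINUTES_PER_DAY) + 0.5) / 60.0  # slot midpoints
    windows = _sleep_windows_for_day(params, rng, s)
    asleep_mask = _window_mask(windows)

    # --- heart rate: cosine + AR(1) noise, small day-level MESOR wobble
    mesor_day = params.hr_mesor + rng.normal(0.0, r["hr_mesor_day_sd"])
    hr_clean = mesor_day + params.hr_amplitude * np.cos(2 * np.pi * (t_hour - params.hr_acrophase) / 24.0)
    if params.hr_noise_sd > 0:
        innov = rng.normal(0.0, params.hr_noise_sd, MINUTES_PER_DAY)
        phi = params.hr_ar1
        noise = lfilter([1.0], [1.0, -phi], innov)
        hr = hr_clean + noise * np.sqrt(1 - phi**2)  # stationary SD = hr_noise_sd
    else:
        hr = hr_clean.copy()
    hr = np.maximum(hr, 35.0)

    # --- steps: zero in sleep, zero-inflated NB with cosine envelope outside
    envelope = 1.0 + r["steps_envelope_depth"] * np.cos(2 * np.pi * (t_hour - params.steps_acrophase) / 24.0)
    lam = params.steps_level * np.maximum(envelope, 0.0)
    size = r["steps_dispersion"]
    p_nb = size / (size + np.maximum(lam, 1e-9))
    steps = rng.negative_binomial(size, p_nb).astype(float)
    steps[rng.random(MINUTES_PER_DAY) < r["steps_zero_prob"]] = 0.0
    steps[asleep_mask] = 0.0

    # --- METs: baseline + bouts while awake, exactly 1.0 asleep
    mets = np.maximum(1.0, a["baseline_met"] + rng.normal(0.0, a["baseline_met_sd"], MINUTES_PER_DAY))
    n_bouts = rng.poisson(params.activity_bout_rate)
    awake_idx = np.flatnonzero(~asleep_mask)
    for _ in range(n_bouts):
        if awake_idx.size == 0:
            break
        start = int(rng.choice(awake_idx))
        dur = max(5, int(rng.exponential(a["bout_duration_mean_min"])))
        level = a["bout_met_median"] * np.exp(rng.normal(0.0, a["bout_met_sigma"]))
        stop = min(start + dur, MINUTES_PER_DAY)
        mets[start:stop] = np.maximum(mets[start:stop], level)
    mets[asleep_mask] = 1.0
    mets = np.minimum(mets, 12.0)

    # --- intensity: ordinal level from the MET cutoffs
    cuts = tree["met_cutoffs"]
    intensity = np.digitize(mets, [cuts["light"], cuts["moderate"], cuts["vigorous"]]).astype(float)

    # --- calories: standard kcal/min conversion from METs and body mass
    calories = mets * 3.5 * profile.weight_kg / 200.0

    # --- sleep epochs over the union of windows
    in_bed_min = np.flatnonzero(asleep_mask)
    starts30 = np.sort(np.concatenate([in_bed_min.astype(float), in_bed_min + 0.5]))
    stages = _sample_stage_runs(starts30.size, rng, s)
    sleep30 = pd.DataFrame({"start_min": starts30, "stage": stages, "in_bed": True})
    states = rng.choice(
        SLEEP60_STATES,
        size=in_bed_min.size,
        p=[
            s["sleep60_asleep_prob"],
            s["sleep60_restless_prob"],
            1.0 - s["sleep60_asleep_prob"] - s["sleep60_restless_prob"],
        ],
    )
    sleep60 = pd.DataFrame({"start_min": np.sort(in_bed_min), "state": states})

    out = DeviceDayStreams(
        subject_id=profile.subject_id,
        date_index=day,
        hr=hr,
        steps=steps,
        intensity=intensity,
        mets=mets,
        calories=calories,
        sleep30=sleep30,
        sleep60=sleep60,
    )
    out.validate()
    return out


def inject_missingness(
    streams: DeviceDayStreams,
    missing_hour_rate: float,
    seed: int | np.random.Generator = 0,
) -> DeviceDayStreams:
    """Blank whole hours of per-minute wear (NaN) at the given rate.

    Sleep epoch tables are untouched: the device logs sleep independently of
    minute-level wear gaps. No data are fabricated; rate 0 is the identity.
    """
    if not 0.0 <= missing_hour_rate <= 1.0:
        raise ValueError("missing_hour_rate must be in [0, 1]")
    out = streams.copy()
    if missing_hour_rate == 0.0:
        return out
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lost_hours = np.flatnonzero(rng.random(24) < missing_hour_rate)
    for h in lost_hours:
        sl = slice(h * 60, (h + 1) * 60)
        for name in ("hr", "steps", "intensity", "mets", "calories"):
            getattr(out, name)[sl] = np.nan
    return out


def generate_dataset(
    spec: CohortSpec,
    cfg: PipelineConfig | dict | None = None,
) -> tuple[list[SubjectProfile], list[DeviceDayStreams]]:
    """Generate the full cohort: profiles plus every subject-day stream."""
    profiles = generate_cohort(spec, cfg)
    tree = _tree(cfg)
    days: list[DeviceDayStreams] = []
    for i, profile in enumerate(profiles):
        params = generate_subject_params(profile, spec, i, tree)
        for d in range(spec.n_days_per_subject):
            rng = _subject_seed(spec.seed, i, d)
            day = generate_day_streams(profile, d, params, cfg=tree, rng=rng)
            day = inject_missingness(day, spec.missing_hour_rate, rng)
            days.append(day)
    return profiles, days


# ---------------------------------------------------------------------------
# canonical CSV dialect


def write_streams_csv(
    profiles: Iterable[SubjectProfile],
    days: Iterable[DeviceDayStreams],
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write the cohort in the repo's long-format CSV dialect.

    Files: ``subjects.csv`` (one row per subject), ``minute_streams.csv``
    (subject_id, date_index, minute, variable, value; missing slots omitted),
    ``sleep30.csv`` and ``sleep60.csv`` epoch tables.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {name: out / f"{name}.csv" for name in ("subjects", "minute_streams", "sleep30", "sleep60")}

    pd.DataFrame([vars(p) for p in profiles]).to_csv(paths["subjects"], index=False)

    minute_rows, s30_rows, s60_rows = [], [], []
    for d in days:
        for var in ("hr", "steps", "intensity", "mets", "calories"):
            arr = getattr(d, var)
            present = np.flatnonzero(~np.isnan(arr))
            minute_rows.append(
                pd.DataFrame(
                    {
                        "subject_id": d.subject_id,
                        "date_index": d.date_index,
                        "minute": present,
                        "variable": var,
                        "value": arr[present],
                    }
                )
            )
        s30 = d.sleep30.assign(subject_id=d.subject_id, date_index=d.date_index)
        s60 = d.sleep60.assign(subject_id=d.subject_id, date_index=d.date_index)
        s30_rows.append(s30)
        s60_rows.append(s60)
    pd.concat(minute_rows, ignore_index=True).to_csv(paths["minute_streams"], index=False)
    pd.concat(s30_rows, ignore_index=True).to_csv(paths["sleep30"], index=False)
    pd.concat(s60_rows, ignore_index=True).to_csv(paths["sleep60"], index=False)
    return paths


# ---------------------------------------------------------------------------
# helpers


def _tree(cfg: PipelineConfig | dict | None) -> dict:
    if cfg is None:
        return load_defaults()
    if isinstance(cfg, PipelineConfig):
        return cfg.to_dict()
    return cfg


def _section(cfg: PipelineConfig | dict | None, name: str) -> dict:
    return _tree(cfg)[name]
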