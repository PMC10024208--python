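import numpy as np
import pandas as pd
import pytest

import wearcirc as wc
from wearcirc.synthetic import MINUTES_PER_DAY


@pytest.fixture(scope="session")
def default_cfg():
    return wc.load_defaults()


@pytest.fixture(scope="session")
def small_cohort():
    """20 subjects x 3 days with group effects; shared across read-only tests."""
    spec = wc.CohortSpec(
        n_subjects=20,
        prevalence=0.3,
        n_days_per_subject=3,
        effect_map=wc.load_defaults()["cohort"]["effect_map"],
        missing_hour_rate=0.05,
        seed=11,
    )
    profiles, days = wc.generate_dataset(spec)
    return spec, profiles, days


@pytest.fixture(scope="session")
def small_dataset(small_cohort):
    _, profiles, days = small_cohort
    return wc.assemble_entries(days, profiles)


@pytest.fixture()
def profile():
    return wc.SubjectProfile(
        subject_id="S00000",
        sex="male",
        age_months=144.0,
        height_cm=150.0,
        weight_kg=47.0,
        diagnosis="control",
    )


def make_day(
    hr=80.0,
    steps=0.0,
    mets=1.0,
    sleep30=None,
    sleep60=None,
    subject_id="S00000",
    date_index=0,
    weight_kg=47.0,
):
    """Hand-built fully-worn day for boundary tests."""

    def arr(v):
        a = np.full(MINUTES_PER_DAY, np.nan) if v is None else np.full(MINUTES_PER_DAY, float(v))
        return a

    hr_a = np.asarray(hr, dtype=float) if np.ndim(hr) else arr(hr)
    steps_a = np.asarray(steps, dtype=float) if np.ndim(steps) else arr(steps)
    mets_a = np.asarray(mets, dtype=float) if np.ndim(mets) else arr(mets)
    intensity = np.digitize(mets_a, [1.5, 3.0, 6.0]).astype(float)
    intensity[np.isnan(mets_a)] = np.nan
    calories = mets_a * 3.5 * weight_kg / 200.0
    if sleep30 is None:
        sleep30 = pd.DataFrame({"start_min": pd.Series(dtype=float), "stage": pd.Series(dtype=str), "in_bed": pd.Series(dtype=bool)})
    if sleep60 is None:
        sleep60 = pd.DataFrame({"start_min": pd.Series(dtype=int), "state": pd.Series(dtype=str)})
    return wc.DeviceDayStreams(
        subject_id=subject_id,
        date_index=date_index,
        hr=hr_a,
        steps=steps_a,
        intensity=intensity,
        mets=mets_a,
        calories=calories,
        sleep30=sleep30,
        sleep60=sleep60,
    )


def sleep30_frame(start_min, stages):
    """In-bed 30-s epochs starting at start_min, one per 0.5 min."""
    starts = start_min + 0.5 * np.arange(len(stages))
    return pd.DataFrame({"start_min": starts % MINUTES_PER_DAY, "stage": list(stages), "in_bed": True}).sort_values(
        "start_min", ignore_index=True
    )


@pytest.fixture()
def toy_feature_frame():
    """Fabricated entry table with registry columns and one informative feature."""
    rng = np.random.default_rng(4)
    n = 480
    frame = pd.DataFrame(rng.normal(size=(n, 64)), columns=list(wc.FEATURE_REGISTRY))
    frame.insert(0, "date_index", np.arange(n) % 4)
    frame.insert(0, "subject_id", [f"S{i // 4:04d}" for i in range(n)])
    lab = (rng.random(n // 4) < 0.15).astype(int)
    frame["label"] = np.repeat(lab, 4)
    frame["sex"] = rng.integers(0, 2, n).astype(float)
    frame["hr_mesor"] = rng.normal(size=n) + 2.0 * frame["label"]
    return frame
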