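"""Two-group cohort statistics: normality screening and comparison tables.

Each feature is screened for normality in both groups with the
Kolmogorov-Smirnov test against a normal with estimated parameters
(Lilliefors correction); when both groups pass, an independent-samples
t test is used, otherwise the Mann-Whitney U test, always two-sided.
Tests run on per-day entries, so within-subject correlation is accepted —
a deliberate, documented simplification. No multiple-testing correction is
applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors

from .assembly import DISPLAY_NAMES, FEATURE_REGISTRY, TrainingDataset

__all__ = ["GroupComparison", "compare_groups", "table1_report"]


@dataclass(frozen=True)
class GroupComparison:
    feature: str
    control_mean: float
    control_sd: float
    case_mean: float
    case_sd: float
    difference: float  # case mean - control mean
    test: str  # "t" | "mann-whitney" | "none"
    p_value: float


def _normalish(x: np.ndarray, alpha: float) -> bool:
    if np.ptp(x) == 0.0:
        return False
    _, p = lilliefors(x, dist="norm")
    return p > alpha


def compare_groups(
    values_control: np.ndarray,
    values_case: np.ndarray,
    feature: str = "",
    alpha_normality: float = 0.05,
) -> GroupComparison:
    """Screened two-group comparison of one feature.

    Requires n >= 3 per group after dropping NaN. Zero variance in both
    groups leaves the p value undefined (reported missing, not a
    placeholder).
    """
    a = np.asarray(values_control, dtype=float)
    b = np.asarray(values_case, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size < 3 or b.size < 3:
        raise ValueError(f"need >= 3 observations per group, got {a.size} and {b.size}")

    stats_ab = dict(
        control_mean=float(a.mean()),
        control_sd=float(a.std(ddof=1)),
        case_mean=float(b.mean()),
        case_sd=float(b.std(ddof=1)),
    )
    if np.ptp(a) == 0.0 and np.ptp(b) == 0.0:
        # degenerate feature: identical-constant groups have p ~ 1,
        # differing constants are trivially separated but untestable here
        p = math.nan
        test = "none"
    elif _normalish(a, alpha_normality) and _normalish(b, alpha_normality):
        _, p = sps.ttest_ind(a, b, equal_var=True)
        test = "t"
    else:
        _, p = sps.mannwhitneyu(a, b, alternative="two-sided")
        test = "mann-whitney"
    return GroupComparison(
        feature=feature,
        difference=stats_ab["case_mean"] - stats_ab["control_mean"],
        test=test,
        p_value=float(p) if not math.isnan(p) else math.nan,
        **stats_ab,
    )


def table1_report(dataset: TrainingDataset | pd.DataFrame, alpha_normality: float = 0.05) -> pd.DataFrame:
    """Per-feature group-comparison table over the per-day entries.

    One row per registry feature (mean (SD) per group, difference, test,
    p value) plus a leading sex row reported as count (%) of male entries
    with a chi-square p value.
    """
    frame = dataset.frame if isinstance(dataset, TrainingDataset) else dataset
    ctrl = frame[frame["label"] == 0]
    case = frame[frame["label"] == 1]
    rows: list[dict] = []

    n_male = (int((ctrl["sex"] == 1).sum()), int((case["sex"] == 1).sum()))
    table = np.array(
        [[n_male[0], len(ctrl) - n_male[0]], [n_male[1], len(case) - n_male[1]]], dtype=float
    )
    if table.min() >= 0 and table.sum(axis=1).min() > 0 and table.sum(axis=0).min() > 0:
        _, sex_p, *_ = sps.chi2_contingency(table)
    else:
        sex_p = math.nan
    rows.append(
        {
            "feature": "sex_male",
            "display_name": "Male, No. (%)",
            "control_mean": 100.0 * n_male[0] / len(ctrl) if len(ctrl) else math.nan,
            "control_sd": math.nan,
            "case_mean": 100.0 * n_male[1] / len(case) if len(case) else math.nan,
            "case_sd": math.nan,
            "difference": math.nan,
            "test": "chi2",
            "p_value": float(sex_p) if not math.isnan(sex_p) else math.nan,
        }
    )

    for feat in FEATURE_REGISTRY:
        a = ctrl[feat].to_numpy(dtype=float)
        b = case[feat].to_numpy(dtype=float)
        try:
            cmp_res = compare_groups(a, b, feature=feat, alpha_normality=alpha_normality)
            row = vars(cmp_res).copy()
        except ValueError:
            row = {
                "feature": feat,
                "control_mean": math.nan,
                "control_sd": math.nan,
                "case_mean": math.nan,
                "case_sd": math.nan,
                "difference": math.nan,
                "test": "none",
                "p_value": math.nan,
            }
        row["display_name"] = DISPLAY_NAMES[feat]
        rows.append(row)
    cols = [
        "feature",
        "display_name",
        "control_mean",
        "control_sd",
        "case_mean",
        "case_sd",
        "difference",
        "test",
        "p_value",
    ]
    return pd.DataFrame(rows)[cols]
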