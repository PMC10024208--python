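"""Cosinor analysis and nonparametric rest-activity rhythm metrics.

The single-component cosinor fits y = M + beta*cos(2*pi*t/tau) +
gamma*sin(2*pi*t/tau) by ordinary least squares; MESOR M is the
rhythm-adjusted mean, amplitude sqrt(beta^2 + gamma^2), acrophase the clock
time of the fitted maximum in [0, 24), and goodness of fit 100 * R^2.

Nonparametric metrics follow the standard actigraphy definitions on hourly
bins: interdaily stability IS (1 = a 24-h profile that repeats perfectly),
intradaily variability IV (approaches 2 for white noise), L5 and M10 the
mean level over the least-active 5-h and most-active 10-h contiguous
windows (wrap-around allowed), and relative amplitude
RA = (M10 - L5)/(M10 + L5).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "CosinorFit",
    "NonparamRhythm",
    "fit_cosinor",
    "nonparam_metrics",
    "hourly_bins",
    "extreme_window_mean",
]


@dataclass(frozen=True)
class CosinorFit:
    mesor: float
    amplitude: float
    acrophase: float  # hours in [0, period)
    gof: float  # percent of variance explained, [0, 100]

    def __post_init__(self) -> None:
        if not math.isnan(self.amplitude) and self.amplitude < 0:
            raise ValueError("amplitude must be nonnegative")


@dataclass(frozen=True)
class NonparamRhythm:
    is_stat: float
    iv_stat: float
    l5: float
    m10: float
    ra: float


class CosinorError(ValueError):
    """Raised when a series cannot support a cosinor fit."""


def fit_cosinor(t_hours: np.ndarray, y: np.ndarray, period: float = 24.0) -> CosinorFit:
    """Least-squares single-cosine fit of a timestamped series.

    Requires at least 3 distinct time points spanning at least half a
    period (otherwise the three parameters are not identifiable and
    :class:`CosinorError` is raised). NaN values are dropped. A constant
    series returns amplitude 0 and goodness of fit 0 by convention.
    """
    t = np.asarray(t_hours, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(t) | np.isnan(y))
    t, y = t[keep], y[keep]
    distinct = np.unique(t)
    if distinct.size < 3 or (distinct.max() - distinct.min()) < period / 2.0:
        raise CosinorError(
            f"cosinor needs >=3 distinct time points spanning >= {period / 2:g} h; "
            f"got {distinct.size} points spanning {0.0 if distinct.size == 0 else distinct.max() - distinct.min():g} h"
        )
    theta = 2.0 * np.pi * t / period
    X = np.column_stack([np.ones_like(t), np.cos(theta), np.sin(theta)])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    mesor, beta, gamma = coef
    amplitude = float(np.hypot(beta, gamma))
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst <= 0.0 or amplitude == 0.0:
        return CosinorFit(mesor=float(mesor), amplitude=0.0, acrophase=0.0, gof=0.0)
    resid = y - X @ coef
    gof = 100.0 * (1.0 - float(np.sum(resid**2)) / sst)
    # fitted maximum of beta*cos(theta) + gamma*sin(theta) is at theta = atan2(gamma, beta)
    acrophase = (math.atan2(gamma, beta) * period / (2.0 * np.pi)) % period
    return CosinorFit(
        mesor=float(mesor),
        amplitude=amplitude,
        acrophase=float(acrophase),
        gof=float(np.clip(gof, 0.0, 100.0)),
    )


def hourly_bins(values: np.ndarray, worn: np.ndarray | None = None, min_minutes: int = 30, how: str = "sum") -> np.ndarray:
    """Collapse a 1440-minute day to 24 hourly bins.

    ``how='sum'`` rescales partial hours to a full 60 minutes; hours with
    fewer than ``min_minutes`` present are NaN.
    """
    x = np.asarray(values, dtype=float).reshape(24, 60)
    present = ~np.isnan(x) if worn is None else (np.asarray(worn).reshape(24, 60) & ~np.isnan(x))
    n = present.sum(axis=1)
    with np.errstate(invalid="ignore"):
        total = np.where(present, x, 0.0).sum(axis=1)
        if how == "sum":
            out = np.where(n > 0, total * (60.0 / np.maximum(n, 1)), np.nan)
        elif how == "mean":
            out = np.where(n > 0, total / np.maximum(n, 1), np.nan)
        else:
            raise ValueError(f"unknown binning mode {how!r}")
    out[n < min_minutes] = np.nan
    return out


def extreme_window_mean(
    profile24: np.ndarray,
    width: int,
    minimize: bool,
    max_missing_frac: float = 0.5,
) -> float:
    """Mean over the extreme contiguous wrap-around window of a 24-h profile.

    Enumerates all 24 circular windows of the given width; windows with more
    than ``max_missing_frac`` missing hours are disqualified. Returns NaN if
    every window is disqualified.
    """
    x = np.asarray(profile24, dtype=float)
    if x.shape != (24,):
        raise ValueError("profile must have 24 hourly values")
    best = math.nan
    for start in range(24):
        idx = (start + np.arange(width)) % 24
        w = x[idx]
        n_missing = int(np.isnan(w).sum())
        if n_missing > max_missing_frac * width:
            continue
        m = float(np.nanmean(w))
        if math.isnan(best) or (m < best if minimize else m > best):
            best = m
    return best


def nonparam_metrics(
    hourly: np.ndarray,
    max_missing_frac: float = 0.5,
) -> NonparamRhythm:
    """IS/IV/L5/M10/RA from an hourly-binned record.

    ``hourly`` is shaped (days, 24) or a flat multiple of 24; NaN marks
    missing hours, which are dropped from the sums with the counts adjusted.
    IS compares the variance of the mean 24-h profile with the total
    variance; IV is the mean squared successive difference over the
    variance (successive pairs spanning a missing hour are skipped). L5/M10
    are taken on the mean 24-h profile. A zero-variance record has IS/IV
    undefined (NaN).
    """
    x = np.asarray(hourly, dtype=float)
    if x.ndim == 1:
        if x.size % 24:
            raise ValueError("flat hourly series length must be a multiple of 24")
        x = x.reshape(-1, 24)
    flat = x.reshape(-1)
    obs = flat[~np.isnan(flat)]
    if obs.size < 24:
        raise ValueError("need at least one complete day of hourly bins")
    grand = obs.mean()
    sst = float(np.sum((obs - grand) ** 2))
    n = obs.size

    profile = np.nanmean(x, axis=0)  # mean 24-h profile across days
    hours_with_data = ~np.isnan(profile)

    if sst <= 0.0:
        is_stat = iv_stat = math.nan
    else:
        h = int(hours_with_data.sum())
        # variance of the hourly-mean profile over variance of all samples
        is_stat = (float(np.nansum((profile - grand) ** 2)) / h) / (sst / n)
        diffs = np.diff(flat)
        ok = ~np.isnan(flat[1:]) & ~np.isnan(flat[:-1])
        n_pairs = int(ok.sum())
        iv_stat = (float(np.sum(diffs[ok] ** 2)) / n_pairs) / (sst / n) if n_pairs else math.nan

    l5 = extreme_window_mean(profile, 5, minimize=True, max_missing_frac=max_missing_frac)
    m10 = extreme_window_mean(profile, 10, minimize=False, max_missing_frac=max_missing_frac)
    denom = m10 + l5
    ra = (m10 - l5) / denom if denom and not math.isnan(denom) and denom > 0 else math.nan
    return NonparamRhythm(is_stat=is_stat, iv_stat=iv_stat, l5=l5, m10=m10, ra=ra)
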