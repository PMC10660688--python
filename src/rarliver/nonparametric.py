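"""Nonparametric rest-activity metrics: IS, IV, L5 midpoint, shift-work flag.

Interdaily stability (IS) is the ratio of hour-of-day variance to total
variance of the hourly activity series — 1 for a perfectly repeating daily
pattern, about 1/d for d days of white noise.  Intradaily variability (IV)
is the normalized mean squared successive difference — about 2 for white
noise, small for a slow smooth rhythm, 4 for a perfectly alternating
series.  Both are computed on 60-min means derived from the 5-min bins (the
dominant convention; the bin width is a keyword).  The L5 midpoint is the
centre of the 5 consecutive hours of the averaged 24 h profile with the
lowest activity, used (via a circular 2-SD rule around the cohort circular
median) as a proxy flag for night shift work / unconventional sleep timing.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "hourly_series", "interdaily_stability", "intradaily_variability",
    "l5_midpoint", "flag_shift_workers", "circular_median_hours",
    "circular_sd_hours", "circular_distance_hours",
]


def hourly_series(bins: pd.DataFrame, bin_minutes: int = 60) -> pd.DataFrame:
    """Aggregate 5-min bins to per-(day, hour) means.

    Returns columns ``day_index``, ``hour`` and ``activity`` (missing where
    all underlying 5-min bins are missing).
    """
    per_hour = bin_minutes // 5
    g = bins.assign(hour=bins["bin_5min"] // per_hour)
    return (g.groupby(["day_index", "hour"], sort=True)["activity"]
            .mean().reset_index())


def interdaily_stability(hourly: pd.DataFrame) -> float:
    """IS = hour-of-day variance over total variance of the hourly series.

    ``IS = [sum_h (xbar_h - xbar)^2 / H] / [sum_i (x_i - xbar)^2 / N]`` with
    ``xbar_h`` the mean over days at hour-of-day ``h``, ``H`` the number of
    hours of day with data and ``N`` the number of non-missing hourly values.
    Returns NaN (with a warning) when the series has zero variance.
    """
    x = hourly.dropna(subset=["activity"])
    if x.empty:
        return np.nan
    grand = x["activity"].mean()
    denom = float(((x["activity"] - grand) ** 2).mean())
    if denom <= 0:
        warnings.warn("zero total variance; IS undefined", stacklevel=2)
        return np.nan
    hour_means = x.groupby("hour")["activity"].mean()
    num = float(((hour_means - grand) ** 2).mean())
    return num / denom


def intradaily_variability(hourly: pd.DataFrame) -> float:
    """IV = mean squared successive difference over variance of hourly values.

    Successive differences are taken only between truly adjacent hours
    (consecutive absolute hour index), so gaps from missing hours or missing
    days never contribute spurious jumps.  Returns NaN with a warning for a
    zero-variance series.
    """
    x = hourly.dropna(subset=["activity"]).sort_values(["day_index", "hour"])
    if x.empty:
        return np.nan
    vals = x["activity"].to_numpy(dtype=float)
    abs_hour = (x["day_index"].to_numpy(dtype=np.int64) * 24
                + x["hour"].to_numpy(dtype=np.int64))
    var = float(np.mean((vals - vals.mean()) ** 2))
    if var <= 0:
        warnings.warn("zero variance; IV undefined", stacklevel=2)
        return np.nan
    adj = np.diff(abs_hour) == 1
    if not adj.any():
        return np.nan
    msd = float(np.mean(np.diff(vals)[adj] ** 2))
    return msd / var


def l5_midpoint(bins: pd.DataFrame, max_missing_frac: float = 0.5):
    """Centre (hours) and mean activity of the least-active 5 h window.

    The 24 h profile is the across-valid-days average of the 5-min bins
    (circular).  All 288 windows of 60 consecutive bins are scanned with
    wraparound; the window with the lowest mean available activity wins,
    ties broken to the earliest start.  Returns ``(nan, nan)`` when more
    than ``max_missing_frac`` of the profile is missing.
    """
    profile = (bins.groupby("bin_5min")["activity"].mean()
               .reindex(range(288)).to_numpy(dtype=float))
    if np.isnan(profile).mean() > max_missing_frac:
        return np.nan, np.nan
    ext = np.concatenate([profile, profile])
    best_start, best_mean = None, np.inf
    for start in range(288):
        window = ext[start:start + 60]
        if np.all(np.isnan(window)):
            continue
        m = np.nanmean(window)
        if m < best_mean - 1e-15:
            best_start, best_mean = start, m
    if best_start is None:
        return np.nan, np.nan
    midpoint = ((best_start + 30) * 5 / 60.0) % 24.0
    return float(midpoint), float(best_mean)


# -- circular statistics on clock hours -------------------------------------

def _to_angle(hours):
    return np.asarray(hours, dtype=float) * (2 * np.pi / 24.0)


def circular_distance_hours(a, b):
    """Shortest clock distance |a - b| on the 24 h circle, in hours."""
    d = np.abs(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % 24.0
    return np.minimum(d, 24.0 - d)


def circular_median_hours(hours) -> float:
    """Circular median: the observed value minimizing total circular distance.

    Ties are broken to the smallest clock time.
    """
    h = np.asarray(hours, dtype=float) % 24.0
    cand = np.unique(h)
    costs = np.array([circular_distance_hours(h, c).sum() for c in cand])
    return float(cand[int(np.argmin(costs))])


def circular_sd_hours(hours) -> float:
    """Circular standard deviation sqrt(-2 ln R) mapped back to hours."""
    ang = _to_angle(np.asarray(hours, dtype=float))
    r = np.abs(np.mean(np.exp(1j * ang)))
    if r >= 1.0:
        return 0.0
    return float(np.sqrt(-2.0 * np.log(r)) * 24.0 / (2 * np.pi))


def flag_shift_workers(l5_midpoints, min_cohort: int = 10) -> np.ndarray:
    """Flag unconventional sleep timing: L5 midpoint beyond 2 circular SDs
    from the cohort circular median (strictly greater, so an all-identical
    cohort flags nobody).  Refuses cohorts smaller than ``min_cohort``.
    """
    h = np.asarray(l5_midpoints, dtype=float)
    ok = np.isfinite(h)
    if ok.sum() < min_cohort:
        raise ValueError(
            f"need at least {min_cohort} L5 midpoints, got {int(ok.sum())}")
    med = circular_median_hours(h[ok])
    sd = circular_sd_hours(h[ok])
    flags = np.zeros(h.shape, dtype=bool)
    flags[ok] = circular_distance_hours(h[ok], med) > 2.0 * sd
    return flags
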