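"""Microclimate summaries for passive-warming (open-top chamber) experiments.

Hourly air-temperature records from one to a few sensors per treatment are
reduced to monthly 24-hr means, minima and maxima with standard errors,
and to the OTC - ambient warming contrast per month.  Aggregation order is
fixed: sensors are averaged with equal weight at each timestamp, the
treatment series is averaged to daily values, and monthly statistics with
their SEs are computed over those daily values.  Thawing degree days (TDD)
summarize season warmth as the sum of above-zero daily mean temperatures
between May 1 and September 30.  PAR series are compared between
treatments only over bright hours (either treatment above a threshold) to
quantify chamber shading.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MonthlySummary",
    "monthly_stats",
    "daily_means",
    "thawing_degree_days",
    "par_percent_difference",
    "TDD_WINDOW",
]

#: thawing-degree-day accumulation window (month, day) inclusive
TDD_WINDOW = ((5, 1), (9, 30))


@dataclass(frozen=True)
class MonthlySummary:
    """Monthly 24-hr temperature statistics for one garden."""

    month: pd.Period
    tmean: dict[str, float]  # per treatment
    tmean_se: dict[str, float]
    tmin: dict[str, float]
    tmin_se: dict[str, float]
    tmax: dict[str, float]
    tmax_se: dict[str, float]
    difference: float | None  # OTC - ambient monthly mean, degC


def _treatment_daily(records: pd.DataFrame) -> pd.DataFrame:
    """Daily mean/min/max per treatment, averaging sensors first."""
    df = records.copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    hourly = (df.groupby(["treatment", "timestamp"], observed=True)["value"]
                .mean().reset_index())
    hourly["date"] = hourly["timestamp"].dt.normalize()
    daily = (hourly.groupby(["treatment", "date"], observed=True)["value"]
                   .agg(["mean", "min", "max"]).reset_index())
    return daily


def monthly_stats(records: pd.DataFrame,
                  require_both: bool = False) -> list[MonthlySummary]:
    """Monthly summaries and OTC - ambient contrasts from hourly records.

    ``records`` needs columns timestamp, value (Tair degC), treatment, and
    optionally sensor (several sensors are averaged per timestamp).  SEs
    are computed over the month's daily values.  A month observed under a
    single treatment gets ``difference=None`` (with a warning when
    ``require_both``).
    """
    import warnings

    daily = _treatment_daily(records)
    daily["month"] = daily["date"].dt.to_period("M")
    out: list[MonthlySummary] = []
    for month, g in daily.groupby("month"):
        stats: dict[str, dict[str, float]] = {
            k: {} for k in ("tmean", "tmean_se", "tmin", "tmin_se",
                            "tmax", "tmax_se")}
        for trt, gt in g.groupby("treatment", observed=True):
            n = len(gt)
            sem = 1.0 / np.sqrt(n) if n > 1 else np.nan
            stats["tmean"][trt] = float(gt["mean"].mean())
            stats["tmean_se"][trt] = float(gt["mean"].std(ddof=1) * sem) if n > 1 else 0.0
            stats["tmin"][trt] = float(gt["min"].mean())
            stats["tmin_se"][trt] = float(gt["min"].std(ddof=1) * sem) if n > 1 else 0.0
            stats["tmax"][trt] = float(gt["max"].mean())
            stats["tmax_se"][trt] = float(gt["max"].std(ddof=1) * sem) if n > 1 else 0.0
        if "OTC" in stats["tmean"] and "ambient" in stats["tmean"]:
            diff = stats["tmean"]["OTC"] - stats["tmean"]["ambient"]
        else:
            diff = None
            if require_both:
                warnings.warn(f"month {month}: only one treatment observed; "
                              "difference omitted")
        out.append(MonthlySummary(
            month=month, tmean=stats["tmean"], tmean_se=stats["tmean_se"],
            tmin=stats["tmin"], tmin_se=stats["tmin_se"],
            tmax=stats["tmax"], tmax_se=stats["tmax_se"], difference=diff))
    return out


def daily_means(records: pd.DataFrame) -> pd.DataFrame:
    """Daily mean Tair from hourly records (sensor-averaged first).

    Returns columns date, tair.
    """
    daily = _treatment_daily(records)
    out = (daily.groupby("date", observed=True)["mean"]
                .mean().reset_index().rename(columns={"mean": "tair"}))
    return out


def thawing_degree_days(daily: pd.DataFrame,
                        window: tuple[tuple[int, int], tuple[int, int]] = TDD_WINDOW,
                        ) -> float:
    """TDD: sum of positive daily mean Tair within the thaw window.

    ``daily`` has columns date, tair.  The window is (month, day) bounds
    applied within each calendar year; an empty window yields 0.
    """
    if len(daily) == 0:
        return 0.0
    df = daily.copy()
    dates = pd.to_datetime(df["date"])
    (m0, d0), (m1, d1) = window
    key = dates.dt.month * 100 + dates.dt.day
    in_window = (key >= m0 * 100 + d0) & (key <= m1 * 100 + d1)
    vals = df.loc[in_window, "tair"].astype(float)
    return float(vals[vals > 0].sum())


def par_percent_difference(ambient: pd.Series, otc: pd.Series,
                           threshold: float = 500.0) -> pd.Series:
    """Monthly percent shading of the OTC relative to ambient PAR.

    Both series are indexed by timestamp and must be time-aligned.  Only
    hours where either treatment exceeds ``threshold`` (umol m-2 s-1)
    count; the statistic is 100 (mean_ambient - mean_otc) / mean_ambient,
    positive when the chamber receives less light.  Months with no
    qualifying hour are NaN.
    """
    amb, o = ambient.align(otc, join="inner")
    bright = np.maximum(amb, o) > threshold
    amb_b, o_b = amb[bright], o[bright]
    months = amb_b.index.to_period("M")
    all_months = amb.index.to_period("M").unique()
    out = {}
    for month in all_months:
        sel = months == month
        if not np.any(sel):
            out[month] = np.nan
            continue
        ma, mo = float(amb_b[sel].mean()), float(o_b[sel].mean())
        out[month] = 100.0 * (ma - mo) / ma if ma != 0 else np.nan
    return pd.Series(out, name="par_pct_difference")
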