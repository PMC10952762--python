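"""Antecedent-window extraction and summary statistics.

A biological sample integrates conditions over some preceding period, so
each high-frequency series is summarised over fixed antecedent windows (1,
5, 10, 20, 30, 60 and 90 days) ending at midnight of the sampling day.
Thirteen statistics cover central tendency (mean, median), peaks (Q90, Q95,
maximum, days exceeding 3 x Q50), troughs (minimum, Q5, Q10) and variation
(coefficient of variation; ranges spanning the central 50%, 80% and 90% of
values).

Windows are half-open ``[midnight - w days, midnight)`` so that any
disturbance on the sampling day itself never contaminates the summary.
Quantiles use linear interpolation between order statistics (the numpy
default, Hyndman-Fan type 7).  Percentile orientation: Q95 is a high value
(peak), Q5 a low value (trough).
"""
from __future__ import annotations

import datetime as dt

import numpy as np

from .types import (HydroSeries, InvalidInputError, SummarySpec,
                    WindowSummary, STATISTICS)

__all__ = ["quantile", "extract_window", "summarise_window",
           "days_exceeding_threshold", "summarise_antecedent"]

#: Summaries with window coverage below this fraction are reported missing.
DEFAULT_MIN_COVERAGE = 0.5


def quantile(values, p: float) -> float:
    """p-th quantile (p in [0,1]) with linear order-statistic interpolation.

    NaN on empty input.  Missing values must be removed by the caller.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        return float("nan")
    if not 0.0 <= p <= 1.0:
        raise InvalidInputError(f"quantile fraction {p} outside [0, 1]")
    return float(np.quantile(values, p, method="linear"))


def extract_window(
    series: HydroSeries, sample_date: dt.date, window_days: int,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Observations in the half-open antecedent window before a sample.

    Returns ``(timestamps, values, coverage)`` where the window is
    ``[00:00 of (sample_date - window_days), 00:00 of sample_date)`` and
    coverage is the fraction of the nominal observation grid present
    (missing values count as absent).
    """
    end = np.datetime64(sample_date, "ns")
    start = end - np.timedelta64(window_days, "D")
    i0 = int(np.searchsorted(series.timestamps, start, side="left"))
    i1 = int(np.searchsorted(series.timestamps, end, side="left"))
    ts = series.timestamps[i0:i1]
    vals = series.values[i0:i1]
    present = np.isfinite(vals)
    expected = window_days * 1440 / series.nominal_resolution
    coverage = float(present.sum() / expected)
    return ts[present], vals[present], coverage


def days_exceeding_threshold(
    values: np.ndarray, timestamps: np.ndarray,
    multiplier: float = 3.0, reference: float | None = None,
) -> int:
    """Number of distinct days whose daily mean strictly exceeds
    ``multiplier x reference`` (reference defaults to the window median)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        return 0
    if reference is None:
        reference = float(np.median(values))
    threshold = multiplier * reference
    days = np.asarray(timestamps, dtype="datetime64[D]")
    uniq, inverse = np.unique(days, return_inverse=True)
    sums = np.bincount(inverse, weights=values)
    counts = np.bincount(inverse)
    daily_means = sums / counts
    return int(np.sum(daily_means > threshold))


def summarise_window(
    values: np.ndarray, timestamps: np.ndarray,
) -> dict[str, float]:
    """All thirteen summary statistics of one window's observations.

    ``cv`` (sample SD / mean) is missing when the mean is non-positive.
    Empty input yields NaN for every statistic.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        return {s: float("nan") for s in STATISTICS}
    q5, q10, q25, q50, q75, q90, q95 = np.quantile(
        values, [0.05, 0.10, 0.25, 0.50, 0.75, 0.90, 0.95], method="linear")
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    return {
        "mean": mean,
        "median": float(q50),
        "min": float(values.min()),
        "max": float(values.max()),
        "Q5": float(q5),
        "Q10": float(q10),
        "Q90": float(q90),
        "Q95": float(q95),
        "cv": sd / mean if mean > 0 else float("nan"),
        "range50": float(q75 - q25),
        "range80": float(q90 - q10),
        "range90": float(q95 - q5),
        "days_exceeding_3xQ50": float(days_exceeding_threshold(
            values, timestamps, reference=float(q50))),
    }


def summarise_antecedent(
    series: HydroSeries,
    sample_date: dt.date,
    specs: list[SummarySpec],
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    previous_sample_date: dt.date | None = None,
) -> list[WindowSummary]:
    """WindowSummary records for one series, one sample date, many specs.

    Statistics are computed once per distinct window length.  Windows with
    coverage below ``min_coverage`` report missing values; windows reaching
    back past the previous sampling occasion are computed but flagged
    ``overlapping``.
    """
    out: list[WindowSummary] = []
    by_window: dict[int, tuple[dict[str, float], int, float]] = {}
    for w in sorted({s.window_days for s in specs}):
        ts, vals, coverage = extract_window(series, sample_date, w)
        stats = (summarise_window(vals, ts) if coverage >= min_coverage
                 else {s: float("nan") for s in STATISTICS})
        by_window[w] = (stats, int(vals.size), coverage)
    for spec in specs:
        stats, n_obs, coverage = by_window[spec.window_days]
        flags = []
        if coverage < min_coverage:
            flags.append(f"coverage {coverage:.2f} below {min_coverage}")
        if (previous_sample_date is not None and
                sample_date - dt.timedelta(days=spec.window_days)
                < previous_sample_date):
            flags.append("overlapping: window reaches past previous occasion")
        value = stats[spec.statistic]
        out.append(WindowSummary(
            site_id=series.site_id, sample_date=sample_date,
            determinand=series.determinand, spec=spec,
            value=None if np.isnan(value) else float(value),
            n_obs=n_obs, coverage=coverage, flags=flags))
    return out
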