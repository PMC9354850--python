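"""Posting-volume time series, hour-of-day profiles, and case correlation.

The central question these summaries answer: does the article output of
official accounts track the epidemic itself?  Daily post counts are aligned
with daily newly confirmed cases and compared by the product-moment
correlation; the hour-of-day histogram locates the editorial publishing peak.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .corpus import Corpus, CorpusError, EpidemicSeries


class TemporalError(ValueError):
    """Raised for invalid temporal inputs (constant series, n < 3, ...)."""


@dataclasses.dataclass(frozen=True)
class CorrelationResult:
    """Pearson r between two aligned daily series, with its two-sided p."""

    r: float
    p_value: float
    n: int

    def __post_init__(self) -> None:
        if not -1.0 <= self.r <= 1.0 + 1e-12:
            raise TemporalError(f"|r| must be <= 1, got {self.r}")
        if not 0.0 <= self.p_value <= 1.0:
            raise TemporalError(f"p must be in [0, 1], got {self.p_value}")
        if self.n < 3:
            raise TemporalError(f"need n >= 3 paired days, got {self.n}")


def _as_daily_series(obj) -> pd.Series:
    if isinstance(obj, EpidemicSeries):
        return obj.to_series()
    if isinstance(obj, pd.Series):
        return obj
    raise TemporalError(f"expected a daily series, got {type(obj).__name__}")


def daily_counts(
    corpus: Corpus,
    account_filter: Iterable[str] | None = None,
    date_range: tuple[dt.date, dt.date] | None = None,
) -> pd.Series:
    """Posts per calendar day, contiguous and zero-filled over the range.

    The range defaults to [earliest, latest] posting date of the filtered
    records; pass ``date_range`` explicitly for empty corpora or fixed
    windows.  The series sums to the number of filtered records inside the
    range.
    """
    if account_filter is not None:
        wanted = set(account_filter)
        unknown = wanted - set(corpus.accounts)
        if unknown:
            raise TemporalError(f"unknown account(s) in filter: {sorted(unknown)}")
        records = [r for r in corpus.records if r.account_id in wanted]
    else:
        records = list(corpus.records)

    dates = [r.posted_date for r in records]
    if date_range is None:
        if not dates:
            return pd.Series(dtype=int, name="posts")
        date_range = (min(dates), max(dates))
    start, end = date_range
    if end < start:
        raise TemporalError(f"invalid date range {start}..{end}")
    index = [start + dt.timedelta(days=i) for i in range((end - start).days + 1)]
    counts = pd.Series(0, index=index, name="posts")
    for d in dates:
        if start <= d <= end:
            counts[d] += 1
    return counts


def hourly_profile(corpus: Corpus, account_filter: Iterable[str] | None = None) -> np.ndarray:
    """24-vector of post counts by clock hour (local time); sums to the
    number of filtered records."""
    if account_filter is not None:
        wanted = set(account_filter)
        unknown = wanted - set(corpus.accounts)
        if unknown:
            raise TemporalError(f"unknown account(s) in filter: {sorted(unknown)}")
        records = [r for r in corpus.records if r.account_id in wanted]
    else:
        records = list(corpus.records)
    profile = np.zeros(24, dtype=int)
    for r in records:
        profile[r.posted_hour] += 1
    return profile


def peak_hour(corpus: Corpus, account_filter: Iterable[str] | None = None) -> int:
    """Modal posting hour (first hour on ties)."""
    return int(np.argmax(hourly_profile(corpus, account_filter)))


def period_summary(series: pd.Series | EpidemicSeries, period_days: int) -> pd.DataFrame:
    """Five-number summary of daily counts per consecutive ``period_days`` block.

    Quartiles use linear interpolation (the inclusive convention); the number
    of periods is ceil(len/period_days) and the last block may be partial.
    Columns: period (1-based), start, n_days, min, q1, median, q3, max.
    """
    daily = _as_daily_series(series)
    if period_days < 1:
        raise TemporalError(f"period_days must be >= 1, got {period_days}")
    if daily.empty:
        raise TemporalError("empty series")
    values = daily.to_numpy(dtype=float)
    rows = []
    n_periods = math.ceil(len(values) / period_days)
    for p in range(n_periods):
        chunk = values[p * period_days : (p + 1) * period_days]
        q0, q1, q2, q3, q4 = np.percentile(chunk, [0, 25, 50, 75, 100], method="linear")
        rows.append(
            {
                "period": p + 1,
                "start": daily.index[p * period_days],
                "n_days": len(chunk),
                "min": q0,
                "q1": q1,
                "median": q2,
                "q3": q3,
                "max": q4,
            }
        )
    return pd.DataFrame(rows)


def pearson(a: pd.Series | EpidemicSeries, b: pd.Series | EpidemicSeries) -> CorrelationResult:
    """Pearson correlation between two daily series aligned on common dates.

    p is two-sided, from t = r * sqrt((n-2)/(1-r^2)) on n-2 degrees of
    freedom.  Errors on fewer than 3 common dates or a constant series.
    """
    sa, sb = _as_daily_series(a), _as_daily_series(b)
    common = sa.index.intersection(sb.index)
    n = len(common)
    if n < 3:
        raise TemporalError(f"need >= 3 common dates, got {n}")
    x = sa.loc[common].to_numpy(dtype=float)
    y = sb.loc[common].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise TemporalError("correlation undefined for a constant series")
    result = stats.pearsonr(x, y)
    return CorrelationResult(r=float(result.statistic), p_value=float(result.pvalue), n=n)
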