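"""Reporting-delay adjustment for provisional trailing weeks.

Death registrations trickle in over several weeks, so counts for the most
recent weeks are incomplete at the time of analysis.  This module
implements a simple multiplicative nowcast: reporting completeness per
delay is estimated from a reporting triangle of fully observed weeks, and
each provisional week's count is inflated by the inverse completeness at
its current delay.  It is a deliberately simple stand-in for richer
nowcasting models and can be bypassed entirely in the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .weeks import EpiWeek, WeeklyCountSeries

#: Default maximum delay: ~3 months of provisional weeks.
DEFAULT_MAX_DELAY = 13


class DelayAdjustmentError(ValueError):
    pass


class ReportingTriangle:
    """Counts by (event week, reporting delay in weeks 0..D).

    ``counts[i, d]`` is the number of deaths occurring in week
    ``first_week + i`` that were reported with delay ``d`` weeks.
    Cumulating along the delay axis is therefore nondecreasing.
    """

    def __init__(self, first_week: EpiWeek, counts):
        arr = np.asarray(counts, dtype=np.int64)
        if arr.ndim != 2 or arr.shape[0] == 0 or arr.shape[1] == 0:
            raise DelayAdjustmentError("triangle must be a nonempty 2-d array")
        if np.any(arr < 0):
            raise DelayAdjustmentError("triangle counts must be nonnegative")
        self.first_week = first_week
        self.counts = arr

    @property
    def max_delay(self) -> int:
        return self.counts.shape[1] - 1

    @property
    def n_weeks(self) -> int:
        return self.counts.shape[0]

    def cumulative(self) -> np.ndarray:
        return np.cumsum(self.counts, axis=1)

    def final_counts(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i in range(self.n_weeks):
            wk = (self.first_week + i).start.isoformat()
            for d in range(self.max_delay + 1):
                rows.append(
                    {"event_week": wk, "delay_weeks": d,
                     "count": int(self.counts[i, d])}
                )
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ReportingTriangle":
        weeks = sorted(pd.to_datetime(df["event_week"]).dt.date.unique())
        first = EpiWeek.from_start(weeks[0])
        n_weeks = (weeks[-1] - weeks[0]).days // 7 + 1
        max_d = int(df["delay_weeks"].max())
        counts = np.zeros((n_weeks, max_d + 1), dtype=np.int64)
        for _, row in df.iterrows():
            i = EpiWeek.from_start(
                pd.to_datetime(row["event_week"]).date()
            ).index - first.index
            counts[i, int(row["delay_weeks"])] = int(row["count"])
        return cls(first, counts)


def estimate_completeness(
    tri: ReportingTriangle, as_of: EpiWeek | None = None
) -> np.ndarray:
    """Pooled reporting completeness per delay.

    ``c[d]`` is the pooled fraction of deaths reported within ``d`` weeks
    of the event week, over event weeks fully observed by ``as_of``
    (all weeks if ``as_of`` is None).  Nondecreasing with ``c[D] = 1``.
    """
    if as_of is None:
        full = np.ones(tri.n_weeks, dtype=bool)
    else:
        idx = tri.first_week.index + np.arange(tri.n_weeks)
        full = idx + tri.max_delay <= as_of.index
    if not full.any():
        raise DelayAdjustmentError("no fully observed event week in triangle")
    cum = tri.cumulative()[full]
    final = tri.final_counts()[full]
    total = final.sum()
    if total <= 0:
        raise DelayAdjustmentError("triangle has no reported deaths")
    return cum.sum(axis=0) / total


def adjust_provisional(
    series: WeeklyCountSeries,
    completeness: np.ndarray,
    as_of: EpiWeek,
) -> tuple[WeeklyCountSeries, np.ndarray]:
    """Inflate provisional trailing counts by inverse completeness.

    Weeks whose delay ``d = as_of - week`` is below the maximum delay are
    scaled to ``round(count / c[d])`` (never below the observed count)
    and flagged provisional; older weeks pass through unchanged.

    Returns the adjusted series and a boolean provisional flag per week.
    """
    c = np.asarray(completeness, dtype=float)
    max_delay = len(c) - 1
    counts = series.counts.copy()
    provisional = np.zeros(len(counts), dtype=bool)
    for pos in range(len(counts)):
        d = as_of.index - series.week_at(pos).index
        if d < 0 or d >= max_delay:
            continue
        if c[d] <= 0:
            raise DelayAdjustmentError(
                f"completeness is 0 at delay {d}; cannot adjust"
            )
        adjusted = int(round(counts[pos] / c[d]))
        counts[pos] = max(counts[pos], adjusted)
        provisional[pos] = True
    return (
        WeeklyCountSeries(series.stratum, series.first_week, counts),
        provisional,
    )
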