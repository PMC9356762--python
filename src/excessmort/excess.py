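"""Excess and exiguous death quantification.

A week is flagged EXCESS when the observed count strictly exceeds the
upper prediction bound, EXIGUOUS when it falls strictly below the lower
bound.  Excess (exiguous) deaths are reported as a *range*: from the
distance to the violated bound (0 if the bound is not violated) up to the
distance to the expected count (0 if the observation is on the other
side of it).  Percentages divide each endpoint by the expected count.

Cumulative summaries sum the weekly range endpoints over a period.  By
default every week contributes its clipped distances whether or not it
was flagged (so an unflagged period can still show a range like 0-3179);
``flagged_only=True`` restricts contributions to flagged weeks.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import pandas as pd

from .farrington import WeeklyEstimate
from .weeks import EpiWeek


class ExcessFlag(str, Enum):
    EXCESS = "EXCESS"
    EXIGUOUS = "EXIGUOUS"
    NONE = "NONE"


def flag_week(observed: float, est: WeeklyEstimate) -> ExcessFlag:
    """EXCESS above the upper bound, EXIGUOUS below the lower (strict)."""
    if observed > est.upper:
        return ExcessFlag.EXCESS
    if observed < est.lower:
        return ExcessFlag.EXIGUOUS
    return ExcessFlag.NONE


def excess_range(observed: float, est: WeeklyEstimate) -> tuple[float, float]:
    """[observed - upper, observed - expected], clipped at 0."""
    return (max(0.0, observed - est.upper), max(0.0, observed - est.expected))


def exiguous_range(observed: float, est: WeeklyEstimate) -> tuple[float, float]:
    """[lower - observed, expected - observed], clipped at 0."""
    return (max(0.0, est.lower - observed), max(0.0, est.expected - observed))


def excess_percentage(
    rng: tuple[float, float], expected: float
) -> tuple[float, float]:
    """Range endpoints as a percentage of the expected count."""
    if expected <= 0:
        raise ValueError(f"expected count must be positive, got {expected}")
    return (100.0 * rng[0] / expected, 100.0 * rng[1] / expected)


@dataclass(frozen=True)
class ExcessResult:
    """Weekly estimate, observation, flag and excess/exiguous ranges."""

    week: EpiWeek
    observed: int
    expected: float
    lower: float
    upper: float
    flag: ExcessFlag
    excess: tuple[float, float]
    exiguous: tuple[float, float]
    excess_pct: tuple[float, float]
    exiguous_pct: tuple[float, float]


def evaluate_week(observed: int, est: WeeklyEstimate) -> ExcessResult:
    """Combine an observation with its weekly estimate."""
    exc = excess_range(observed, est)
    exg = exiguous_range(observed, est)
    return ExcessResult(
        week=est.week,
        observed=int(observed),
        expected=est.expected,
        lower=est.lower,
        upper=est.upper,
        flag=flag_week(observed, est),
        excess=exc,
        exiguous=exg,
        excess_pct=excess_percentage(exc, est.expected),
        exiguous_pct=excess_percentage(exg, est.expected),
    )


@dataclass(frozen=True)
class CumulativeSummary:
    """Endpoint-wise sums of weekly ranges over a period."""

    first_week: EpiWeek
    last_week: EpiWeek
    observed_total: int
    excess: tuple[float, float]
    exiguous: tuple[float, float]
    n_excess_weeks: int
    n_exiguous_weeks: int


def cumulate(
    results: Sequence[ExcessResult],
    period: tuple[EpiWeek, EpiWeek] | None = None,
    *,
    flagged_only: bool = False,
) -> CumulativeSummary:
    """Sum weekly excess/exiguous ranges endpoint-wise over a period.

    With ``flagged_only=False`` (default) unflagged weeks contribute
    their clipped distances — 0 to the low endpoint and
    ``max(0, observed - expected)`` to the high endpoint; with
    ``flagged_only=True`` only flagged weeks contribute.
    """
    if period is not None:
        lo, hi = period
        sel = [r for r in results if lo.index <= r.week.index <= hi.index]
    else:
        sel = list(results)
    if not sel:
        raise ValueError("no results in the requested period")
    exc_lo = exc_hi = exg_lo = exg_hi = 0.0
    for r in sel:
        if flagged_only and r.flag is not ExcessFlag.EXCESS:
            pass
        else:
            exc_lo += r.excess[0]
            exc_hi += r.excess[1]
        if flagged_only and r.flag is not ExcessFlag.EXIGUOUS:
            continue
        exg_lo += r.exiguous[0]
        exg_hi += r.exiguous[1]
    return CumulativeSummary(
        first_week=sel[0].week,
        last_week=sel[-1].week,
        observed_total=sum(r.observed for r in sel),
        excess=(exc_lo, exc_hi),
        exiguous=(exg_lo, exg_hi),
        n_excess_weeks=sum(r.flag is ExcessFlag.EXCESS for r in sel),
        n_exiguous_weeks=sum(r.flag is ExcessFlag.EXIGUOUS for r in sel),
    )


def excess_runs(
    results: Sequence[ExcessResult],
) -> list[tuple[EpiWeek, EpiWeek]]:
    """Maximal runs of consecutive EXCESS-flagged weeks.

    Results must be gapless and ordered.  Each run is reported as
    (first flagged week, last flagged week); callers wanting calendar
    dates use ``run[0].start`` and ``run[1].end``.
    """
    for a, b in zip(results, results[1:]):
        if b.week.index != a.week.index + 1:
            raise ValueError("results must form a gapless weekly axis")
    runs: list[tuple[EpiWeek, EpiWeek]] = []
    start: EpiWeek | None = None
    for r in results:
        if r.flag is ExcessFlag.EXCESS:
            if start is None:
                start = r.week
            last = r.week
        elif start is not None:
            runs.append((start, last))
            start = None
    if start is not None:
        runs.append((start, last))
    return runs


# ---------------------------------------------------------------------------
# tabular output (one file per stratum)

_COLUMNS = [
    "week_start", "observed", "expected", "lower", "upper", "flag",
    "excess_low", "excess_high", "exiguous_low", "exiguous_high",
    "excess_pct_low", "excess_pct_high", "exiguous_pct_low", "exiguous_pct_high",
]


def results_to_frame(results: Iterable[ExcessResult]) -> pd.DataFrame:
    """Weekly results as a table; deaths to 2 decimals, percentages to 2."""
    rows = []
    for r in results:
        rows.append(
            {
                "week_start": r.week.start.isoformat(),
                "observed": r.observed,
                "expected": round(r.expected, 2),
                "lower": round(r.lower, 2),
                "upper": round(r.upper, 2),
                "flag": r.flag.value,
                "excess_low": round(r.excess[0], 2),
                "excess_high": round(r.excess[1], 2),
                "exiguous_low": round(r.exiguous[0], 2),
                "exiguous_high": round(r.exiguous[1], 2),
                "excess_pct_low": round(r.excess_pct[0], 2),
                "excess_pct_high": round(r.excess_pct[1], 2),
                "exiguous_pct_low": round(r.exiguous_pct[0], 2),
                "exiguous_pct_high": round(r.exiguous_pct[1], 2),
            }
        )
    return pd.DataFrame(rows, columns=_COLUMNS)
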