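"""Simulation experiments: interval calibration and episode recovery.

These are the package's own validation studies, run both by the test
suite and by ``scripts/acceptance.py``.  They measure (a) the empirical
coverage of the two-sided weekly prediction interval on null series with
no injected episodes, and (b) the power to flag a short multiplicative
excess episode.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np

from .excess import ExcessFlag, flag_week
from .farrington import FarringtonConfig, _estimate_at
from .simulate import Episode, ScenarioParams
from .weeks import week_of

#: History + evaluation layout of the calibration study: 6 years of
#: history then 52 scored weeks.
NULL_N_HISTORY = 6 * 52
NULL_N_EVAL = 52

_FIRST = week_of(dt.date(2014, 1, 6))


def null_scenario(
    seed: int,
    *,
    mu: float = 1000.0,
    k: float = 50.0,
    beta: float = 5e-4,
    amplitude: float = 0.1,
    n_weeks: int = NULL_N_HISTORY + NULL_N_EVAL,
) -> ScenarioParams:
    """Seasonal negative-binomial scenario with no excess episodes."""
    return ScenarioParams(
        n_weeks=n_weeks,
        first_week=_FIRST,
        alpha=float(np.log(mu)),
        beta=beta,
        amplitude=amplitude,
        phase=0.0,
        k=k,
        episodes=(),
        seed=seed,
    )


@dataclass(frozen=True)
class CoverageResult:
    coverage_pct: float
    upper_exceed_pct: float
    lower_exceed_pct: float
    n_weeks: int


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n) % (2**31)


def null_coverage(
    n_series: int = 500,
    seed: int = 0,
    cfg: FarringtonConfig | None = None,
    n_eval: int = NULL_N_EVAL,
) -> CoverageResult:
    """Empirical coverage of the weekly prediction interval on null data.

    Simulates ``n_series`` independent null series, scores the last
    ``n_eval`` weeks of each with the full per-week chain, and reports
    the percentage of scored weeks whose observed count lies within
    [lower, upper], plus the one-sided exceedance rates.
    """
    if cfg is None:
        cfg = FarringtonConfig()
    inside = above = below = total = 0
    from .simulate import simulate_series

    for child in _child_seeds(seed, n_series):
        p = null_scenario(int(child))
        series, _ = simulate_series(p)
        counts = series.counts
        for pos in range(p.n_weeks - n_eval, p.n_weeks):
            est, _ = _estimate_at(counts, pos, cfg)
            y = counts[pos]
            total += 1
            if y > est.upper:
                above += 1
            elif y < est.lower:
                below += 1
            else:
                inside += 1
    return CoverageResult(
        coverage_pct=100.0 * inside / total,
        upper_exceed_pct=100.0 * above / total,
        lower_exceed_pct=100.0 * below / total,
        n_weeks=total,
    )


@dataclass(frozen=True)
class PowerResult:
    prop_ge3_of_4: float
    prop_le1_of_4: float
    mean_flagged: float
    n_reps: int


def episode_power(
    n_reps: int = 200,
    multiplier: float = 1.15,
    seed: int = 0,
    *,
    mu: float = 5000.0,
    k: float = 5000.0,
    episode_len: int = 4,
    cfg: FarringtonConfig | None = None,
) -> PowerResult:
    """Recovery of a short multiplicative excess episode.

    Each replicate simulates 6 years of history followed by a
    ``episode_len``-week episode with the given mean multiplier, scores
    exactly the episode weeks, and counts how many are flagged EXCESS.
    """
    if cfg is None:
        cfg = FarringtonConfig()
    n_hist = NULL_N_HISTORY
    flagged_counts = []
    from .simulate import simulate_series

    for child in _child_seeds(seed, n_reps):
        p = ScenarioParams(
            n_weeks=n_hist + episode_len,
            first_week=_FIRST,
            alpha=float(np.log(mu)),
            beta=2e-4,
            amplitude=0.05,
            phase=0.0,
            k=k,
            episodes=(Episode(n_hist, episode_len, multiplier),),
            seed=int(child),
        )
        series, _ = simulate_series(p)
        counts = series.counts
        n_flag = 0
        for pos in range(n_hist, n_hist + episode_len):
            est, _ = _estimate_at(counts, pos, cfg)
            if flag_week(counts[pos], est) is ExcessFlag.EXCESS:
                n_flag += 1
        flagged_counts.append(n_flag)
    arr = np.array(flagged_counts)
    return PowerResult(
        prop_ge3_of_4=float(np.mean(arr >= 3)),
        prop_le1_of_4=float(np.mean(arr <= 1)),
        mean_flagged=float(arr.mean()),
        n_reps=n_reps,
    )
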