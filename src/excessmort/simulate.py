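"""Synthetic mortality data with the structure the baseline model assumes.

The real input — individual death records from national vital statistics —
is access-restricted, so every stage of the package is exercised on
synthetic data instead.  The generator draws weekly counts from a
negative-binomial law whose mean follows a log-linear trend plus an
annual sinusoid::

    mu_t = exp(alpha + beta * t + A * sin(2 pi t / 52.1775 + psi))

optionally multiplied by episode factors (m > 1 injects excess weeks,
m < 1 exiguous ones).  The negative binomial realises quasi-Poisson-style
overdispersion (variance ``mu + mu^2/k``); ``k = None`` gives the Poisson
limit.  The annual period is 365.25/7 = 52.1775 weeks, deliberately
mismatched to the fitting side's categorical seasonality to exercise the
model's robustness.

Record-level simulation distributes each week's count uniformly over the
week's seven days with ICD-10 codes drawn from a per-category pool, so
re-aggregating the records reproduces the weekly counts exactly.  Delay
thinning assigns each death an independent reporting delay and returns
both the provisionally visible counts and the true reporting triangle.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .delay import ReportingTriangle
from .icd import CauseCategory
from .weeks import (
    NON_COVID_ALL,
    EpiWeek,
    Place,
    Stratum,
    WeeklyCountSeries,
    week_of,
)

#: Annual period of the seasonal sinusoid, in weeks (365.25 / 7).
ANNUAL_PERIOD_WEEKS = 365.25 / 7.0

#: Example ICD-10 code pools per cause category, for record-level output.
DEFAULT_CODE_POOLS: dict[str, list[str]] = {
    CauseCategory.RESPIRATORY.value: ["J12.9", "J18.0", "J44", "J69.0", "J96"],
    CauseCategory.CIRCULATORY.value: ["I21.9", "I50", "I63.9", "I10", "I71"],
    CauseCategory.MALIGNANT_NEOPLASM.value: ["C16", "C34.9", "C50", "C61", "C80"],
    CauseCategory.SENILITY.value: ["R54"],
    CauseCategory.COVID19.value: ["U07.1"],
    CauseCategory.OTHER.value: ["A41.9", "E14", "K70.3", "N18", "X59"],
}

#: Default weekly axis: the study-style window, the week containing
#: 2012-01-01 (which starts in late December 2011) through late May 2021.
DEFAULT_FIRST_WEEK = week_of(dt.date(2012, 1, 1))  # starts 2011-12-26
DEFAULT_N_WEEKS = week_of(dt.date(2021, 5, 30)).index - DEFAULT_FIRST_WEEK.index + 1


@dataclass(frozen=True)
class Episode:
    """A multi-week multiplicative departure from the baseline mean.

    ``start`` is the week offset from the start of the series; weeks
    ``start .. start+length-1`` have their mean multiplied by
    ``multiplier`` (> 1 excess, < 1 exiguous).
    """

    start: int
    length: int
    multiplier: float

    def __post_init__(self):
        if self.length < 1 or self.multiplier < 0:
            raise ValueError("episode needs length >= 1 and multiplier >= 0")


@dataclass(frozen=True)
class ScenarioParams:
    """Parameters of one synthetic weekly count series.

    ``alpha`` is the baseline log-mean (log deaths/week), ``beta`` the
    weekly log-linear trend, ``amplitude``/``phase`` the annual sinusoid,
    ``k`` the negative-binomial size (None = Poisson).
    """

    n_weeks: int = DEFAULT_N_WEEKS
    first_week: EpiWeek = DEFAULT_FIRST_WEEK
    alpha: float = float(np.log(1000.0))
    beta: float = 0.0
    amplitude: float = 0.0
    phase: float = 0.0
    k: float | None = None
    episodes: tuple[Episode, ...] = ()
    seed: int = 0

    def __post_init__(self):
        if self.n_weeks < 1:
            raise ValueError("n_weeks must be >= 1")
        if self.k is not None and self.k <= 0:
            raise ValueError("negative-binomial size k must be positive")
        for ep in self.episodes:
            if ep.start < 0 or ep.start + ep.length > self.n_weeks:
                raise ValueError("episode window outside the series")

    def mean(self) -> np.ndarray:
        """Baseline mean per week, before episode multipliers."""
        t = np.arange(self.n_weeks, dtype=float)
        return np.exp(
            self.alpha
            + self.beta * t
            + self.amplitude
            * np.sin(2.0 * np.pi * t / ANNUAL_PERIOD_WEEKS + self.phase)
        )

    def multipliers(self) -> np.ndarray:
        m = np.ones(self.n_weeks)
        for ep in self.episodes:
            m[ep.start : ep.start + ep.length] *= ep.multiplier
        return m


@dataclass(frozen=True)
class GroundTruth:
    """True mean structure behind a simulated series."""

    mu: np.ndarray              # episode-free baseline mean
    multipliers: np.ndarray     # episode multipliers per week
    episode_weeks: np.ndarray   # boolean mask of weeks inside any episode


_DEFAULT_STRATUM = Stratum(NON_COVID_ALL, Place.ALL, "JP")


def simulate_series(
    p: ScenarioParams, stratum: Stratum = _DEFAULT_STRATUM
) -> tuple[WeeklyCountSeries, GroundTruth]:
    """Draw one weekly count series; identical seed+params => identical data."""
    rng = np.random.default_rng(p.seed)
    mu = p.mean()
    mult = p.multipliers()
    mean = mu * mult
    if p.k is None or np.isinf(p.k):
        counts = rng.poisson(mean)
    else:
        counts = rng.negative_binomial(p.k, p.k / (p.k + mean))
    truth = GroundTruth(mu=mu, multipliers=mult, episode_weeks=mult != 1.0)
    return WeeklyCountSeries(stratum, p.first_week, counts), truth


def simulate_records(
    p: ScenarioParams,
    stratum: Stratum,
    code_pool: list[str] | None = None,
) -> tuple[pd.DataFrame, WeeklyCountSeries, GroundTruth]:
    """Record-level deaths whose weekly totals equal ``simulate_series``.

    ``stratum`` must name a concrete place of death (records cannot carry
    the ALL pseudo-place) and a concrete cause category for the code
    pool; dates are uniform within each week.
    """
    if stratum.place is Place.ALL:
        raise ValueError("record-level simulation needs a concrete place")
    if code_pool is None:
        if stratum.cause == NON_COVID_ALL:
            raise ValueError(
                "NON_COVID_ALL has no single code pool; pass code_pool"
            )
        code_pool = DEFAULT_CODE_POOLS[stratum.cause]
    series, truth = simulate_series(p, stratum)
    rng = np.random.default_rng([p.seed, 1])  # independent of count draws
    rows = []
    for pos, n in enumerate(series.counts):
        if n == 0:
            continue
        start = series.week_at(pos).start
        day_offsets = rng.integers(0, 7, size=n)
        codes = rng.choice(code_pool, size=n)
        for off, code in zip(day_offsets, codes):
            rows.append(
                {
                    "date": (start + dt.timedelta(days=int(off))).isoformat(),
                    "icd10": str(code),
                    "place": stratum.place.value,
                    "region": stratum.region,
                }
            )
    df = pd.DataFrame(rows, columns=["date", "icd10", "place", "region"])
    return df, series, truth


def thin_by_delay(
    series: WeeklyCountSeries,
    delay_probs,
    as_of: EpiWeek,
    seed: int = 0,
) -> tuple[WeeklyCountSeries, ReportingTriangle]:
    """Assign each death an independent reporting delay and censor at ``as_of``.

    ``delay_probs[d]`` is the probability a death is reported ``d`` weeks
    after its event week (must sum to 1).  Returns the provisional series
    (reports landing after ``as_of`` removed) and the *true* reporting
    triangle for round-trip testing.
    """
    probs = np.asarray(delay_probs, dtype=float)
    if probs.ndim != 1 or np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("delay law must be nonnegative and sum to 1")
    rng = np.random.default_rng([seed, 2])
    n_weeks = len(series)
    tri = np.zeros((n_weeks, len(probs)), dtype=np.int64)
    visible = np.zeros(n_weeks, dtype=np.int64)
    for pos in range(n_weeks):
        n = int(series.counts[pos])
        if n == 0:
            continue
        tri[pos] = rng.multinomial(n, probs)
        max_d = as_of.index - series.week_at(pos).index
        if max_d >= 0:
            visible[pos] = tri[pos, : min(max_d, len(probs) - 1) + 1].sum()
    provisional = WeeklyCountSeries(series.stratum, series.first_week, visible)
    return provisional, ReportingTriangle(series.first_week, tri)


# ---------------------------------------------------------------------------
# scenario files


@dataclass(frozen=True)
class ScenarioStratum:
    stratum: Stratum
    params: ScenarioParams
    code_pool: list[str] | None = None


def load_scenario(path) -> list[ScenarioStratum]:
    """Read a multi-stratum scenario from structured text (YAML).

    Top-level keys ``first_week`` (ISO Monday), ``n_weeks`` and ``seed``
    apply to every stratum; each entry of ``strata`` gives ``cause``,
    ``place``, ``region``, the mean-model parameters and optionally
    ``codes`` and ``episodes`` (``[start, length, multiplier]`` triples).
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    first = (
        EpiWeek.from_start(dt.date.fromisoformat(str(doc["first_week"])))
        if "first_week" in doc
        else DEFAULT_FIRST_WEEK
    )
    n_weeks = int(doc.get("n_weeks", DEFAULT_N_WEEKS))
    base_seed = int(doc.get("seed", 0))
    out = []
    for i, entry in enumerate(doc["strata"]):
        stratum = Stratum(
            str(entry["cause"]),
            Place.from_text(entry.get("place", "all")),
            str(entry.get("region", "JP")),
        )
        episodes = tuple(
            Episode(int(s), int(length), float(m))
            for s, length, m in entry.get("episodes", [])
        )
        params = ScenarioParams(
            n_weeks=n_weeks,
            first_week=first,
            alpha=float(entry["alpha"]),
            beta=float(entry.get("beta", 0.0)),
            amplitude=float(entry.get("amplitude", 0.0)),
            phase=float(entry.get("phase", 0.0)),
            k=(float(entry["k"]) if entry.get("k") is not None else None),
            episodes=episodes,
            seed=base_seed + i,
        )
        out.append(
            ScenarioStratum(stratum, params, entry.get("codes"))
        )
    return out
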