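"""Orchestration: run the full analysis grid and summarise periods.

``run_analysis`` walks every stratum in a weekly-count table, applies the
optional reporting-delay adjustment, fits the Farrington baseline for
each evaluation week, quantifies excess/exiguous deaths, and writes one
weekly table and one runs report per stratum plus a cumulative summary
and a JSON run manifest.  Per-stratum failures are recorded in the
manifest without aborting the grid.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .delay import ReportingTriangle, adjust_provisional, estimate_completeness
from .excess import (
    CumulativeSummary,
    ExcessResult,
    cumulate,
    evaluate_week,
    excess_runs,
    results_to_frame,
)
from .farrington import BaselineMode, FarringtonConfig, TrendMode, estimate_week
from .weeks import EpiWeek, Stratum, WeeklyCountSeries, read_counts, week_of

logger = logging.getLogger(__name__)


@dataclass
class RunManifest:
    """Resolved configuration plus per-stratum terminal status."""

    config: dict
    input_digests: dict[str, str]
    strata: dict[str, dict]
    version: str = __version__

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=str)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _farrington_config(config: dict, cause: str) -> FarringtonConfig:
    base = dict(config.get("farrington", {}))
    overrides = config.get("per_cause_overrides", {}).get(cause, {})
    base.update(overrides)
    if "trend_mode" in base:
        base["trend_mode"] = TrendMode(base["trend_mode"])
    if "baseline_mode" in base:
        base["baseline_mode"] = BaselineMode(base["baseline_mode"])
    return FarringtonConfig(**base)


def analyze_stratum(
    series: WeeklyCountSeries,
    eval_weeks: list[EpiWeek],
    cfg: FarringtonConfig,
) -> list[ExcessResult]:
    """Per-week Farrington fit and excess quantification for one series."""
    results = []
    for week in eval_weeks:
        est = estimate_week(series, week, cfg)
        observed = int(series.counts[series.position_of(week)])
        results.append(evaluate_week(observed, est))
    return results


def run_analysis(
    config: dict | str | Path,
    counts_path,
    out_dir,
    *,
    delay_adjustment: bool | None = None,
) -> dict[Stratum, list[ExcessResult]]:
    """Run the analysis grid described by ``config`` over a counts table.

    Config keys: ``farrington`` (FarringtonConfig fields),
    ``per_cause_overrides`` (e.g. ``{RESPIRATORY: {b: 3}}``),
    ``evaluation`` (``start``/``end`` dates of the scoring window) and
    optionally ``delay`` (``enabled``, ``triangle`` path, ``as_of``).
    Deterministic given identical inputs and config.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    series_map = read_counts(counts_path)
    ev = config["evaluation"]
    eval_first = week_of(_as_date(ev["start"]))
    eval_last = week_of(_as_date(ev["end"]))
    eval_weeks = [
        EpiWeek(i) for i in range(eval_first.index, eval_last.index + 1)
    ]

    delay_cfg = config.get("delay", {})
    if delay_adjustment is None:
        delay_adjustment = bool(delay_cfg.get("enabled", False))
    completeness = None
    as_of = None
    if delay_adjustment:
        tri = ReportingTriangle.from_frame(pd.read_csv(delay_cfg["triangle"]))
        as_of = week_of(_as_date(delay_cfg["as_of"]))
        completeness = estimate_completeness(tri, as_of)

    manifest = RunManifest(
        config=_jsonable_config(config, delay_adjustment),
        input_digests={"counts": _sha256(counts_path)},
        strata={},
    )
    all_results: dict[Stratum, list[ExcessResult]] = {}
    summary_rows = []
    for stratum, series in series_map.items():
        cfg = _farrington_config(config, stratum.cause)
        status: dict = {"b": cfg.b, "w": cfg.w, "status": "ok"}
        try:
            if completeness is not None:
                series, provisional = adjust_provisional(
                    series, completeness, as_of
                )
                status["provisional_weeks"] = int(provisional.sum())
            results = analyze_stratum(series, eval_weeks, cfg)
        except Exception as exc:  # per-stratum failure never aborts the grid
            logger.warning("stratum %s failed: %s", stratum.label(), exc)
            status["status"] = "failed"
            status["error"] = str(exc)
            manifest.strata[stratum.label()] = status
            continue
        all_results[stratum] = results
        status["weeks_flagged_excess"] = sum(
            r.flag.value == "EXCESS" for r in results
        )
        status["weeks_flagged_exiguous"] = sum(
            r.flag.value == "EXIGUOUS" for r in results
        )
        manifest.strata[stratum.label()] = status

        results_to_frame(results).to_csv(
            out / f"weekly_{stratum.label()}.csv", index=False
        )
        runs = excess_runs(results)
        pd.DataFrame(
            [
                {"run_start": a.start.isoformat(), "run_end": b.end.isoformat()}
                for a, b in runs
            ],
            columns=["run_start", "run_end"],
        ).to_csv(out / f"runs_{stratum.label()}.csv", index=False)
        summary_rows.append(
            _summary_row(stratum, cumulate(results))
        )

    pd.DataFrame(summary_rows, columns=_SUMMARY_COLUMNS).to_csv(
        out / "cumulative_summary.csv", index=False
    )
    (out / "manifest.json").write_text(manifest.to_json())
    return all_results


_SUMMARY_COLUMNS = [
    "cause", "place", "region", "period_start", "period_end", "observed",
    "excess_low", "excess_high", "exiguous_low", "exiguous_high",
]


def _summary_row(stratum: Stratum, summ: CumulativeSummary) -> dict:
    return {
        "cause": stratum.cause,
        "place": stratum.place.value,
        "region": stratum.region,
        "period_start": summ.first_week.start.isoformat(),
        "period_end": summ.last_week.end.isoformat(),
        "observed": summ.observed_total,
        "excess_low": round(summ.excess[0]),
        "excess_high": round(summ.excess[1]),
        "exiguous_low": round(summ.exiguous[0]),
        "exiguous_high": round(summ.exiguous[1]),
    }


def summarize_period(
    results: dict[Stratum, list[ExcessResult]],
    first: EpiWeek,
    last: EpiWeek,
    *,
    flagged_only: bool = False,
) -> pd.DataFrame:
    """Cumulative observed/excess/exiguous table over a period, per stratum."""
    rows = []
    for stratum, res in results.items():
        summ = cumulate(res, (first, last), flagged_only=flagged_only)
        rows.append(_summary_row(stratum, summ))
    return pd.DataFrame(rows, columns=_SUMMARY_COLUMNS)


def _as_date(value) -> dt.date:
    if isinstance(value, dt.date):
        return value
    return dt.date.fromisoformat(str(value))


def _jsonable_config(config: dict, delay_adjustment: bool) -> dict:
    resolved = json.loads(json.dumps(config, default=str))
    resolved["delay_adjustment_applied"] = delay_adjustment
    return resolved
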