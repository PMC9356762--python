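"""Monday-start epidemiological weeks and stratified weekly count series.

All time indexing in the package is in whole weeks running Monday through
Sunday.  An :class:`EpiWeek` is identified by its integer position on a
continuous weekly axis (week 0 starts Monday 1970-01-05), so week
arithmetic is plain integer arithmetic and year boundaries need no special
handling — the few days of the previous calendar year that fall in the
first analysis week simply belong to that week.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .icd import CauseCategory, classify_cause

logger = logging.getLogger(__name__)

_EPOCH = dt.date(1970, 1, 5)  # a Monday

#: Pseudo-cause for the all-cause-excluding-COVID-19 series.
NON_COVID_ALL = "NON_COVID_ALL"


class Place(str, Enum):
    """Place-of-death category from the death certificate."""

    ALL = "all"
    HOSPITAL_CLINIC = "hospital_clinic"
    NURSING_ELDERLY = "nursing_elderly"
    HOME = "home"
    OTHER = "other"

    @classmethod
    def from_text(cls, text: str) -> "Place":
        return cls(str(text).strip().lower())


#: The four concrete places whose series sum to the ALL series.
SPECIFIC_PLACES = (
    Place.HOSPITAL_CLINIC,
    Place.NURSING_ELDERLY,
    Place.HOME,
    Place.OTHER,
)


@dataclass(frozen=True, order=True)
class EpiWeek:
    """A Monday-start calendar week on the continuous weekly axis."""

    index: int

    @property
    def start(self) -> dt.date:
        """The Monday on which the week begins."""
        return _EPOCH + dt.timedelta(days=7 * self.index)

    @property
    def end(self) -> dt.date:
        """The Sunday on which the week ends."""
        return self.start + dt.timedelta(days=6)

    @classmethod
    def from_start(cls, d: dt.date) -> "EpiWeek":
        if d.weekday() != 0:
            raise ValueError(f"{d} is not a Monday")
        return cls(index=(d - _EPOCH).days // 7)

    def __add__(self, k: int) -> "EpiWeek":
        return EpiWeek(self.index + int(k))

    def __sub__(self, other: "EpiWeek | int"):
        if isinstance(other, EpiWeek):
            return self.index - other.index
        return EpiWeek(self.index - int(other))

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return self.start.isoformat()


def week_of(d: dt.date) -> EpiWeek:
    """Week containing ``d``: the greatest Monday not after ``d``."""
    monday = d - dt.timedelta(days=d.weekday())
    return EpiWeek(index=(monday - _EPOCH).days // 7)


def week_range(first: EpiWeek, last: EpiWeek) -> list[EpiWeek]:
    """Inclusive list of weeks from ``first`` through ``last``."""
    if last.index < first.index:
        raise ValueError("last week precedes first week")
    return [EpiWeek(i) for i in range(first.index, last.index + 1)]


@dataclass(frozen=True)
class Stratum:
    """One analysis stratum: cause group x place of death x region.

    ``cause`` is a :class:`~excessmort.icd.CauseCategory` value or the
    special :data:`NON_COVID_ALL`; ``region`` is a free-text code
    (``"JP"`` national, or a prefecture code).
    """

    cause: str
    place: Place
    region: str

    def __post_init__(self):
        valid = {c.value for c in CauseCategory} | {NON_COVID_ALL}
        if self.cause not in valid:
            raise ValueError(f"unknown cause stratum {self.cause!r}")

    def label(self) -> str:
        return f"{self.cause}_{self.place.value}_{self.region}"

    def matches_cause(self, category: CauseCategory) -> bool:
        if self.cause == NON_COVID_ALL:
            return category is not CauseCategory.COVID19
        return category.value == self.cause


class WeeklyCountSeries:
    """Observed death counts per week for one stratum.

    The weekly axis is gapless by construction; ``counts[i]`` belongs to
    week ``first_week + i``.  Counts must be nonnegative integers.
    """

    def __init__(self, stratum: Stratum, first_week: EpiWeek, counts):
        arr = np.asarray(counts)
        if arr.ndim != 1 or len(arr) == 0:
            raise ValueError("counts must be a nonempty 1-d array")
        if not np.all(np.isfinite(arr)) or np.any(arr < 0):
            raise ValueError("counts must be finite and nonnegative")
        if not np.all(arr == np.floor(arr)):
            raise ValueError("counts must be integral")
        self.stratum = stratum
        self.first_week = first_week
        self.counts = arr.astype(np.int64)

    def __len__(self) -> int:
        return len(self.counts)

    @property
    def last_week(self) -> EpiWeek:
        return self.first_week + (len(self.counts) - 1)

    @property
    def weeks(self) -> list[EpiWeek]:
        return [self.first_week + i for i in range(len(self.counts))]

    def week_at(self, pos: int) -> EpiWeek:
        return self.first_week + pos

    def position_of(self, week: EpiWeek) -> int:
        pos = week.index - self.first_week.index
        if not 0 <= pos < len(self.counts):
            raise KeyError(f"week {week.start} outside series")
        return pos

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "week_start": [w.start.isoformat() for w in self.weeks],
                "cause": self.stratum.cause,
                "place": self.stratum.place.value,
                "region": self.stratum.region,
                "deaths": self.counts,
            }
        )


class AggregationError(ValueError):
    """Raised when death records cannot be aggregated into weekly counts."""


def _classify_series(codes: pd.Series) -> pd.Series:
    """Vectorised cause classification (cache per unique code)."""
    uniq = {c: classify_cause(c) for c in codes.unique()}
    return codes.map(uniq)


def aggregate_records(
    records: pd.DataFrame,
    first_week: EpiWeek,
    last_week: EpiWeek,
    strata: Sequence[Stratum],
    *,
    regions: Iterable[str] | None = None,
) -> dict[Stratum, WeeklyCountSeries]:
    """Aggregate record-level deaths into gapless weekly count series.

    ``records`` needs columns ``date`` (ISO-8601 or date), ``icd10``,
    ``place`` and ``region``.  Records outside ``first_week..last_week``
    are dropped with a logged count.  Each requested stratum receives one
    series over the full axis; weeks with no matching deaths carry 0.
    Records whose cause classifies as COVID-19 are excluded from
    :data:`NON_COVID_ALL` strata.

    Raises
    ------
    AggregationError
        If a record carries an unknown place (or, when ``regions`` is
        given, an unknown region); the message lists offending records.
    """
    df = records.copy()
    dates = pd.to_datetime(df["date"]).dt.date
    widx = np.array([week_of(d).index for d in dates])

    try:
        place_vals = df["place"].map(Place.from_text)
    except ValueError:
        bad = df.loc[
            ~df["place"].astype(str).str.strip().str.lower().isin(
                [p.value for p in Place]
            )
        ]
        raise AggregationError(
            f"unknown place value(s) in {len(bad)} record(s): "
            f"{bad.head(10).to_dict('records')}"
        )
    if (place_vals == Place.ALL).any():
        bad = df.loc[place_vals == Place.ALL]
        raise AggregationError(
            "record-level place must be a specific location, not 'all': "
            f"{bad.head(10).to_dict('records')}"
        )
    if regions is not None:
        known = set(regions)
        bad = df.loc[~df["region"].isin(known)]
        if len(bad):
            raise AggregationError(
                f"unknown region value(s) in {len(bad)} record(s): "
                f"{bad.head(10).to_dict('records')}"
            )

    in_range = (widx >= first_week.index) & (widx <= last_week.index)
    n_dropped = int((~in_range).sum())
    if n_dropped:
        logger.info("dropped %d record(s) outside configured week range", n_dropped)
    df = df.loc[in_range]
    widx = widx[in_range]
    place_vals = place_vals[in_range]

    categories = _classify_series(df["icd10"])
    n_weeks = last_week.index - first_week.index + 1
    offsets = (widx - first_week.index).astype(np.int64)

    out: dict[Stratum, WeeklyCountSeries] = {}
    for stratum in strata:
        mask = categories.map(stratum.matches_cause).to_numpy(dtype=bool)
        if stratum.place is not Place.ALL:
            mask &= (place_vals == stratum.place).to_numpy(dtype=bool)
        if stratum.region != "ALL":
            mask &= (df["region"] == stratum.region).to_numpy(dtype=bool)
        counts = np.bincount(offsets[mask], minlength=n_weeks)
        out[stratum] = WeeklyCountSeries(stratum, first_week, counts)
    return out


# ---------------------------------------------------------------------------
# delimited-text I/O


def read_records(path) -> pd.DataFrame:
    """Read record-level deaths: columns date,icd10,place,region."""
    df = pd.read_csv(path, dtype={"icd10": str, "region": str})
    missing = {"date", "icd10", "place", "region"} - set(df.columns)
    if missing:
        raise AggregationError(f"record file missing column(s): {sorted(missing)}")
    return df


def write_records(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False)


def write_counts(series_map: Mapping[Stratum, WeeklyCountSeries], path) -> None:
    """Write weekly counts: columns week_start,cause,place,region,deaths."""
    frames = [s.to_frame() for s in series_map.values()]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_counts(path) -> dict[Stratum, WeeklyCountSeries]:
    """Read weekly counts back into per-stratum series.

    Each stratum's weekly axis must be gapless and strictly ordered.
    """
    df = pd.read_csv(path, dtype={"region": str})
    out: dict[Stratum, WeeklyCountSeries] = {}
    for (cause, place, region), grp in df.groupby(
        ["cause", "place", "region"], sort=False
    ):
        stratum = Stratum(cause, Place.from_text(place), str(region))
        starts = pd.to_datetime(grp["week_start"]).dt.date
        idx = np.array([EpiWeek.from_start(d).index for d in starts])
        order = np.argsort(idx)
        idx = idx[order]
        if len(idx) > 1 and not np.all(np.diff(idx) == 1):
            raise AggregationError(
                f"weekly axis for stratum {stratum.label()} has gaps or duplicates"
            )
        counts = grp["deaths"].to_numpy()[order]
        out[stratum] = WeeklyCountSeries(stratum, EpiWeek(int(idx[0])), counts)
    return out
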