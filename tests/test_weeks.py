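"""Monday-week calendar arithmetic and record aggregation."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from excessmort.weeks import (
    NON_COVID_ALL,
    AggregationError,
    EpiWeek,
    Place,
    SPECIFIC_PLACES,
    Stratum,
    WeeklyCountSeries,
    aggregate_records,
    read_counts,
    week_of,
    write_counts,
)


@pytest.mark.parametrize(
    "date,monday",
    [
        (dt.date(2021, 5, 5), dt.date(2021, 5, 3)),
        (dt.date(2021, 5, 3), dt.date(2021, 5, 3)),  # Monday maps to itself
        (dt.date(2019, 12, 31), dt.date(2019, 12, 30)),
        (dt.date(2012, 1, 1), dt.date(2011, 12, 26)),  # year boundary
    ],
)
def test_week_of(date, monday):
    wk = week_of(date)
    assert wk.start == monday
    assert wk.end == monday + dt.timedelta(days=6)


@given(st.dates(min_value=dt.date(1990, 1, 1), max_value=dt.date(2100, 1, 1)),
       st.integers(min_value=0, max_value=6))
@settings(max_examples=200, derandomize=True)
def test_week_of_constant_within_week_and_idempotent(monday_ish, offset):
    wk = week_of(monday_ish)
    assert wk.start.weekday() == 0
    assert week_of(wk.start + dt.timedelta(days=offset)) == wk
    assert week_of(wk.start) == wk  # idempotent on Mondays
    assert (wk + 1).start - wk.start == dt.timedelta(days=7)


def _records(rows):
    return pd.DataFrame(rows, columns=["date", "icd10", "place", "region"])


def test_aggregate_counts_three_records_in_one_week():
    recs = _records(
        [
            ("2021-05-04", "I21", "home", "JP"),
            ("2021-05-05", "I50", "home", "JP"),
            ("2021-05-09", "I63", "home", "JP"),
        ]
    )
    wk = week_of(dt.date(2021, 5, 3))
    stratum = Stratum("CIRCULATORY", Place.HOME, "JP")
    out = aggregate_records(recs, wk, wk + 3, [stratum])
    assert list(out[stratum].counts) == [3, 0, 0, 0]


def test_aggregate_empty_records_gives_zero_series():
    wk = week_of(dt.date(2021, 5, 3))
    stratum = Stratum(NON_COVID_ALL, Place.ALL, "ALL")
    out = aggregate_records(_records([]), wk, wk + 3, [stratum])
    assert list(out[stratum].counts) == [0, 0, 0, 0]


def test_non_covid_all_excludes_covid_records():
    recs = _records(
        [
            ("2021-05-04", "U07.1", "home", "JP"),
            ("2021-05-05", "C50", "home", "JP"),
            ("2021-05-06", "I21", "home", "JP"),
        ]
    )
    wk = week_of(dt.date(2021, 5, 3))
    stratum = Stratum(NON_COVID_ALL, Place.ALL, "ALL")
    out = aggregate_records(recs, wk, wk, [stratum])
    assert out[stratum].counts[0] == 2


def test_aggregation_conserves_records():
    """Place-specific series sum to ALL; categories sum to record count."""
    rng = np.random.default_rng(7)
    wk = week_of(dt.date(2020, 1, 6))
    n = 400
    codes = rng.choice(["J12", "I50", "C50", "R54", "U07.1", "A41", "X59"], n)
    places = rng.choice([p.value for p in SPECIFIC_PLACES], n)
    days = [wk.start + dt.timedelta(days=int(d)) for d in rng.integers(0, 56, n)]
    recs = _records(
        [(d.isoformat(), c, p, "JP") for d, c, p in zip(days, codes, places)]
    )
    all_stratum = Stratum(NON_COVID_ALL, Place.ALL, "JP")
    place_strata = [Stratum(NON_COVID_ALL, p, "JP") for p in SPECIFIC_PLACES]
    cause_strata = [
        Stratum(c, Place.ALL, "JP")
        for c in ["RESPIRATORY", "CIRCULATORY", "MALIGNANT_NEOPLASM",
                  "SENILITY", "COVID19", "OTHER"]
    ]
    out = aggregate_records(
        recs, wk, wk + 7, [all_stratum] + place_strata + cause_strata
    )
    place_sum = sum(out[s].counts for s in place_strata)
    assert np.array_equal(place_sum, out[all_stratum].counts)
    cause_sum = sum(out[s].counts for s in cause_strata)
    assert cause_sum.sum() == n


def test_unknown_place_raises_listing_records():
    recs = _records([("2021-05-04", "I21", "hospice", "JP")])
    wk = week_of(dt.date(2021, 5, 3))
    with pytest.raises(AggregationError, match="place"):
        aggregate_records(recs, wk, wk, [Stratum(NON_COVID_ALL, Place.ALL, "ALL")])


def test_unknown_region_raises_when_vocabulary_declared():
    recs = _records([("2021-05-04", "I21", "home", "Atlantis")])
    wk = week_of(dt.date(2021, 5, 3))
    with pytest.raises(AggregationError, match="region"):
        aggregate_records(
            recs, wk, wk, [Stratum(NON_COVID_ALL, Place.ALL, "ALL")],
            regions=["JP"],
        )


def test_records_outside_range_are_dropped():
    recs = _records(
        [("2021-05-04", "I21", "home", "JP"), ("2020-01-01", "I21", "home", "JP")]
    )
    wk = week_of(dt.date(2021, 5, 3))
    stratum = Stratum(NON_COVID_ALL, Place.ALL, "ALL")
    out = aggregate_records(recs, wk, wk, [stratum])
    assert out[stratum].counts.sum() == 1


def test_counts_roundtrip_through_csv(tmp_path):
    stratum = Stratum("SENILITY", Place.HOME, "13")
    series = WeeklyCountSeries(stratum, week_of(dt.date(2020, 1, 6)), [1, 0, 4])
    path = tmp_path / "counts.csv"
    write_counts({stratum: series}, path)
    back = read_counts(path)
    assert list(back[stratum].counts) == [1, 0, 4]
    assert back[stratum].first_week == series.first_week


def test_series_rejects_invalid_counts():
    stratum = Stratum("SENILITY", Place.HOME, "13")
    wk = week_of(dt.date(2020, 1, 6))
    with pytest.raises(ValueError):
        WeeklyCountSeries(stratum, wk, [1, -1])
    with pytest.raises(ValueError):
        WeeklyCountSeries(stratum, wk, [1.5, 2])
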