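"""Petrel-year calendar conventions.

The breeding colony is active all year round, with a minimum of activity in
May, so the annual calendar ("petrel year") starts on 1 June and days are
numbered from that origin: 1 June = day 1, 2 June = day 2, ... up to 365 or
366 (when the petrel year contains a 29 February).

Event dates that straddle the 1 June origin within one individual's repeated
events (e.g. arriving on 30 May one year and 2 June the next) are converted
to signed days — dates just before the origin become small negative values —
so that arithmetic on the circular variable is meaningful.

Seasons follow the monsoon circulation of the western Indian Ocean:
austral winter = May–September, austral summer = October–April.
"""

from __future__ import annotations

import datetime as dt
from typing import Iterable, Sequence

ORIGIN_MONTH = 6
ORIGIN_DAY = 1

WINTER_MONTHS = frozenset({5, 6, 7, 8, 9})


def _as_date(d) -> dt.date:
    if isinstance(d, dt.datetime):
        return d.date()
    if isinstance(d, dt.date):
        return d
    raise TypeError(f"expected date, got {type(d).__name__}")


def petrel_year_start(date) -> dt.date:
    """Return the 1 June that starts the petrel year containing `date`."""
    date = _as_date(date)
    y = date.year if (date.month, date.day) >= (ORIGIN_MONTH, ORIGIN_DAY) else date.year - 1
    return dt.date(y, ORIGIN_MONTH, ORIGIN_DAY)


def petrel_year_length(date) -> int:
    """Days in the petrel year containing `date` (365, or 366 if it spans a 29 Feb)."""
    start = petrel_year_start(date)
    return (dt.date(start.year + 1, ORIGIN_MONTH, ORIGIN_DAY) - start).days


def day_index(date) -> int:
    """Day number within the petrel year: 1 June -> 1, 2 June -> 2, ..."""
    date = _as_date(date)
    return (date - petrel_year_start(date)).days + 1


def day_index_to_date(index: int, petrel_year: int) -> dt.date:
    """Inverse of :func:`day_index` for the petrel year starting 1 June `petrel_year`.

    `index` may be negative or exceed the year length; the date is extended
    linearly (day 0 = 31 May, day -1 = 30 May, ...).
    """
    return dt.date(petrel_year, ORIGIN_MONTH, ORIGIN_DAY) + dt.timedelta(days=int(index) - 1)


def season_of(date_or_month) -> str:
    """Classify a date (or month number) as 'winter' (May–Sep) or 'summer' (Oct–Apr)."""
    if isinstance(date_or_month, int):
        month = date_or_month
        if not 1 <= month <= 12:
            raise ValueError(f"month out of range: {month}")
    else:
        month = _as_date(date_or_month).month
    return "winter" if month in WINTER_MONTHS else "summer"


def season_of_day_index(index: int, petrel_year: int = 2015) -> str:
    """Season of a petrel-year day index (petrel year only matters for leap years)."""
    return season_of(day_index_to_date(index, petrel_year))


def to_signed_days(dates: Sequence) -> list[int]:
    """Convert one individual's repeated event dates to signed petrel-year days.

    If the dates straddle the 1 June origin (some just before, some just
    after), the pre-origin dates are mapped to ``day_index - year_length``
    (e.g. 30 May = day 364 -> -1) so that the spread of the values reflects
    the true circular spread. The encoding (all-positive vs signed) with the
    smaller spread is kept; ties keep the positive encoding.
    """
    dates = [_as_date(d) for d in dates]
    if not dates:
        raise ValueError("to_signed_days requires at least one date")
    plain = [day_index(d) for d in dates]
    signed = []
    for d, idx in zip(dates, plain):
        length = petrel_year_length(d)
        # candidate negative encoding: late days wrap to negative
        signed.append(idx - length if idx > length / 2 else idx)
    spread_plain = max(plain) - min(plain)
    spread_signed = max(signed) - min(signed)
    return signed if spread_signed < spread_plain else plain


def signed_days(values: Iterable, ids: Iterable) -> list[int]:
    """Apply :func:`to_signed_days` independently per individual.

    `values` are dates; `ids` the matching individual identifiers. Returns
    signed days in the original order.
    """
    values = list(values)
    ids = list(ids)
    if len(values) != len(ids):
        raise ValueError("values and ids must have equal length")
    out: list[int | None] = [None] * len(values)
    for ind in set(ids):
        pos = [k for k, i in enumerate(ids) if i == ind]
        conv = to_signed_days([values[k] for k in pos])
        for k, v in zip(pos, conv):
            out[k] = v
    return out  # type: ignore[return-value]
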