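"""Calendar handling.

All in-memory tables carry dates as integer day offsets from EPOCH
(2020-01-01); calendar parsing and formatting are confined to the readers
and writers in :mod:`rxlink.io`.  Integer arithmetic keeps day differences
exact and makes the synthetic generator byte-reproducible.
"""

from __future__ import annotations

import datetime as _dt

import pandas as pd

EPOCH = _dt.date(2020, 1, 1)


def to_offset(d: _dt.date | str) -> int:
    """Convert a calendar date (or ISO-8601 string) to a day offset."""
    if isinstance(d, str):
        d = _dt.date.fromisoformat(d)
    return (d - EPOCH).days


def to_date(offset: int) -> _dt.date:
    return EPOCH + _dt.timedelta(days=int(offset))


def year_interval(year: int) -> tuple[int, int]:
    """Inclusive (first_day, last_day) offsets of a calendar year."""
    return to_offset(_dt.date(year, 1, 1)), to_offset(_dt.date(year, 12, 31))


def offsets_to_iso(s: pd.Series) -> pd.Series:
    """Vectorised offset -> ISO-8601 date string."""
    return (pd.Timestamp(EPOCH) + pd.to_timedelta(s.astype("int64"), unit="D")).dt.strftime(
        "%Y-%m-%d"
    )


def iso_to_offsets(s: pd.Series) -> pd.Series:
    """Vectorised ISO-8601 date string -> integer offset."""
    return (pd.to_datetime(s, format="%Y-%m-%d") - pd.Timestamp(EPOCH)).dt.days.astype("int64")


def age_years(birth_offset: int, ref_offset: int) -> int:
    """Whole years between two day offsets, using a 365-day year.

    The synthetic generator writes birth dates so that this is exact; real
    calendars would need month-aware arithmetic in the reader layer.
    """
    return (int(ref_offset) - int(birth_offset)) // 365
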