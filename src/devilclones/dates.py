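"""Decimal-year date conventions.

All sampling dates, node dates and event dates in this package are decimal
years (e.g. 2014-07-01 -> 2014.497).  The fractional part is the elapsed
fraction of that calendar year, so leap years divide by 366.
"""

from __future__ import annotations

import datetime as _dt

__all__ = ["to_decimal_year", "from_decimal_year"]


def to_decimal_year(date: _dt.date | str) -> float:
    """Convert a calendar date (or ISO string) to a decimal year."""
    if isinstance(date, str):
        date = _dt.date.fromisoformat(date)
    start = _dt.date(date.year, 1, 1)
    end = _dt.date(date.year + 1, 1, 1)
    return date.year + (date - start).days / (end - start).days


def from_decimal_year(year: float) -> _dt.date:
    """Convert a decimal year back to the calendar date it falls in."""
    whole = int(year)
    start = _dt.date(whole, 1, 1)
    ndays = (_dt.date(whole + 1, 1, 1) - start).days
    return start + _dt.timedelta(days=int(round((year - whole) * ndays)))
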