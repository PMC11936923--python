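"""Partial calendar dates as they appear in spontaneous-report databases.

FAERS date fields are numeric strings of 8 (YYYYMMDD), 6 (YYYYMM) or 4
(YYYY) digits; any of them may be blank.  Day arithmetic is only defined
for full-precision dates.
"""
from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from typing import Optional

DAY = "day"
MONTH = "month"
YEAR = "year"


@dataclass(frozen=True, order=True)
class PartialDate:
    """A possibly incomplete date, stored as a padded 8-digit integer.

    ``value`` pads missing components with 01 (e.g. ``202203`` becomes
    ``20220301`` with precision ``month``), which keeps ordering sensible
    while ``precision`` records what was actually reported.
    """

    value: int
    precision: str = DAY

    def to_date(self) -> _dt.date:
        if self.precision != DAY:
            raise ValueError(f"date {self.value} has {self.precision} precision")
        v = self.value
        return _dt.date(v // 10000, (v // 100) % 100, v % 100)

    def isoformat(self) -> str:
        v = self.value
        if self.precision == YEAR:
            return f"{v // 10000:04d}"
        if self.precision == MONTH:
            return f"{v // 10000:04d}-{(v // 100) % 100:02d}"
        return f"{v // 10000:04d}-{(v // 100) % 100:02d}-{v % 100:02d}"


def parse_partial_date(raw: object) -> Optional[PartialDate]:
    """Parse a FAERS date string; return ``None`` for blank or unparseable.

    Accepts YYYYMMDD, YYYYMM and YYYY.  Calendar-invalid full dates (e.g.
    month 13) are treated as unparseable rather than silently coerced.
    """
    if raw is None:
        return None
    s = str(raw).strip()
    if not s or s.lower() in {"nan", "none"}:
        return None
    if s.endswith(".0"):  # numeric round-trip through floats
        s = s[:-2]
    if not s.isdigit():
        return None
    if len(s) == 4:
        return PartialDate(int(s) * 10000 + 101, YEAR)
    if len(s) == 6:
        y, m = int(s[:4]), int(s[4:6])
        if not 1 <= m <= 12:
            return None
        return PartialDate(int(s) * 100 + 1, MONTH)
    if len(s) == 8:
        y, m, d = int(s[:4]), int(s[4:6]), int(s[6:8])
        try:
            _dt.date(y, m, d)
        except ValueError:
            return None
        return PartialDate(int(s), DAY)
    return None


def days_between(start: PartialDate, end: PartialDate) -> int:
    """Signed day count from ``start`` to ``end`` (both full precision)."""
    return (end.to_date() - start.to_date()).days
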