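"""Spreadsheet 1900-system serial-date arithmetic and display-date parsing.

Spreadsheets store dates internally as integer serial numbers counting days
from the 1900 epoch (serial 1 = 1 Jan 1900), including a phantom 29 Feb 1900
at serial 60 kept for Lotus 1-2-3 compatibility.  When a date cell is
reformatted as number or text, the serial leaks out as a five-digit number,
which is why ``43709`` in a gene column is really 1 Sep 2019.

This module is the foundation for five-digit-number detection and for
reverse-mapping flagged cells back to gene symbols.
"""

from __future__ import annotations

import datetime as dt
import re
from dataclasses import dataclass
from typing import Optional, Sequence

from .months import ENGLISH, MonthTable, month_abbrev

__all__ = [
    "PHANTOM_SERIAL",
    "MIN_SERIAL",
    "MAX_SERIAL",
    "DEFAULT_SERIAL_WINDOW",
    "InvalidSerialError",
    "DateOutOfRangeError",
    "DisplayDate",
    "DateDialect",
    "serial_to_date",
    "date_to_serial",
    "parse_display_date",
    "is_candidate_serial",
]

#: Phantom 29 Feb 1900; maps to no real calendar date.
PHANTOM_SERIAL = 60
MIN_SERIAL = 1
#: 31 Dec 9999 in the 1900 system.
MAX_SERIAL = 2958465
#: Default plausibility window for five-digit serial candidates.
DEFAULT_SERIAL_WINDOW = (10000, 99999)

# Serials 1..59 precede the phantom leap day; 61+ follow it.
_EPOCH_BELOW = dt.date(1899, 12, 31)
_EPOCH_ABOVE = dt.date(1899, 12, 30)
_EPOCH_1904 = dt.date(1904, 1, 1)


class InvalidSerialError(ValueError):
    """Serial is out of range or the phantom 29 Feb 1900."""


class DateOutOfRangeError(ValueError):
    """Calendar date falls outside the representable serial range."""


def serial_to_date(serial: int, *, system_1904: bool = False) -> dt.date:
    """Convert an integer day serial to a calendar date.

    Parameters
    ----------
    serial
        Integer serial in [1, 2958465] and not 60 (the phantom leap day).
    system_1904
        Use the alternative 1904 epoch (serial 0 = 1 Jan 1904).  Off by
        default; the 1900 system is what produces five-digit gene dates.

    Raises
    ------
    InvalidSerialError
        For serial 60 or out-of-range serials.
    """
    serial = int(serial)
    if system_1904:
        try:
            return _EPOCH_1904 + dt.timedelta(days=serial)
        except OverflowError as exc:
            raise InvalidSerialError(f"serial out of range: {serial}") from exc
    if serial == PHANTOM_SERIAL:
        raise InvalidSerialError(
            "serial 60 is the phantom 29 Feb 1900 and maps to no real date"
        )
    if not MIN_SERIAL <= serial <= MAX_SERIAL:
        raise InvalidSerialError(f"serial out of range [1, {MAX_SERIAL}]: {serial}")
    epoch = _EPOCH_ABOVE if serial >= 61 else _EPOCH_BELOW
    return epoch + dt.timedelta(days=serial)


def date_to_serial(date: dt.date, *, system_1904: bool = False) -> int:
    """Inverse of :func:`serial_to_date`.

    Raises :class:`DateOutOfRangeError` for dates before the epoch.
    """
    if isinstance(date, dt.datetime):
        date = date.date()
    if system_1904:
        if date < _EPOCH_1904:
            raise DateOutOfRangeError(f"date precedes 1904 epoch: {date}")
        return (date - _EPOCH_1904).days
    if date < dt.date(1900, 1, 1):
        raise DateOutOfRangeError(f"date precedes 1 Jan 1900: {date}")
    if date < dt.date(1900, 3, 1):
        return (date - _EPOCH_BELOW).days
    return (date - _EPOCH_ABOVE).days


def is_candidate_serial(
    serial: int, window: tuple[int, int] = DEFAULT_SERIAL_WINDOW
) -> bool:
    """True iff *serial* lies in the five-digit plausibility *window*.

    The default window accepts any five-digit value; pass a narrower window
    (e.g. serials for 2010-2029) to restrict flagging to recent decades.
    """
    lo, hi = window
    return lo <= int(serial) <= hi


@dataclass(frozen=True)
class DisplayDate:
    """A date as displayed in a cell; month is always present.

    ``alternate`` carries the swapped day/month reading of an ambiguous
    slash date (e.g. 3/1/2016) so downstream reporting is not misled.
    """

    month: int
    day: Optional[int] = None
    year: Optional[int] = None
    source_format: str = "d-mmm"
    alternate: Optional["DisplayDate"] = None

    def __post_init__(self) -> None:
        if not 1 <= self.month <= 12:
            raise ValueError(f"month out of range: {self.month}")
        if self.day is not None and not 1 <= self.day <= 31:
            raise ValueError(f"day out of range: {self.day}")

    def render(self) -> str:
        if self.source_format == "mmm-yy":
            return f"{month_abbrev(self.month)}-{(self.year or 0) % 100:02d}"
        if self.source_format == "mmm-d":
            return f"{month_abbrev(self.month)}-{self.day:02d}"
        if self.source_format == "iso" and self.year is not None:
            return f"{self.year:04d}-{self.month:02d}-{self.day:02d}"
        if self.source_format == "slash" and self.year is not None:
            return f"{self.month}/{self.day}/{self.year}"
        return f"{self.day}-{month_abbrev(self.month)}"


@dataclass(frozen=True)
class DateDialect:
    """Configuration for display-date parsing.

    day_first controls the reading of slash dates (3/1/2016); the default
    month-first matches US-locale spreadsheets.  Two-digit years below
    ``year_pivot`` land in the 2000s, the rest in the 1900s.
    """

    day_first: bool = False
    year_pivot: int = 30
    tables: Sequence[MonthTable] = (ENGLISH,)

    def expand_year(self, two_digit: int) -> int:
        return 2000 + two_digit if two_digit < self.year_pivot else 1900 + two_digit

    def month_for(self, token: str) -> Optional[int]:
        for table in self.tables:
            month = table.lookup(token)
            if month is not None:
                return month
        return None


DEFAULT_DIALECT = DateDialect()

_ISO_RE = re.compile(r"^(\d{4})-(\d{1,2})-(\d{1,2})$")
_SLASH_RE = re.compile(r"^(\d{1,2})/(\d{1,2})/(\d{2}|\d{4})$")
_D_MMM_RE = re.compile(r"^(\d{1,2})[-/. ]([^\W\d_]+)\.?$")
_MMM_N_RE = re.compile(r"^([^\W\d_]+)\.?[-/. ](\d{1,2})$")


def parse_display_date(
    text: str, dialect: DateDialect = DEFAULT_DIALECT
) -> Optional[DisplayDate]:
    """Parse a trimmed cell string as a displayed date, or return None.

    Recognized shapes: ``3-Mar`` (d-mmm), ``Mar-3`` / ``Mar-03`` (mmm-d),
    ``Jan-41`` (mmm-yy, number 32-99 read as a two-digit year), slash dates
    such as ``3/1/2016``, and ISO dates.  Month tokens come from the
    dialect's month tables (English by default).  Non-dates return None.
    """
    text = text.strip()
    if not text:
        return None

    match = _ISO_RE.match(text)
    if match:
        year, month, day = (int(g) for g in match.groups())
        if 1 <= month <= 12 and 1 <= day <= 31:
            return DisplayDate(month=month, day=day, year=year, source_format="iso")
        return None

    match = _SLASH_RE.match(text)
    if match:
        first, second, year_txt = match.groups()
        a, b = int(first), int(second)
        year = int(year_txt)
        if len(year_txt) == 2:
            year = dialect.expand_year(year)
        day, month = (a, b) if dialect.day_first else (b, a)
        primary = _checked_slash(month, day, year)
        if primary is None:
            # Fall back to the swapped reading, e.g. 25/12/2016 month-first.
            return _checked_slash(day, month, year)
        if a != b and a <= 12 and b <= 12:
            alternate = _checked_slash(day, month, year)
            if alternate is not None:
                primary = DisplayDate(
                    month=primary.month,
                    day=primary.day,
                    year=primary.year,
                    source_format="slash",
                    alternate=alternate,
                )
        return primary

    match = _D_MMM_RE.match(text)
    if match:
        day = int(match.group(1))
        month = dialect.month_for(match.group(2))
        if month is not None and 1 <= day <= 31:
            return DisplayDate(month=month, day=day, source_format="d-mmm")
        return None

    match = _MMM_N_RE.match(text)
    if match:
        month = dialect.month_for(match.group(1))
        if month is None:
            return None
        n = int(match.group(2))
        if 1 <= n <= 31:
            return DisplayDate(month=month, day=n, source_format="mmm-d")
        if 32 <= n <= 99:
            return DisplayDate(
                month=month, year=dialect.expand_year(n), source_format="mmm-yy"
            )
        return None

    return None


def _checked_slash(month: int, day: int, year: int) -> Optional[DisplayDate]:
    if 1 <= month <= 12 and 1 <= day <= 31:
        return DisplayDate(month=month, day=day, year=year, source_format="slash")
    return None
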