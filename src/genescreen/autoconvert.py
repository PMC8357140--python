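"""Deterministic simulation of spreadsheet autoconversion.

Models the text-file-open import path: a month token joined to a small
integer becomes a date (SEPT7 → 7-Sep, TAMM41 → Jan-41), and digits+E+digits
identifiers become floating-point numbers (2310009E13 → 2.310009E+19).
Everything else passes through unchanged.  Used both to screen gene-name
catalogues for vulnerable symbols and to build ground-truth fixtures.
"""

from __future__ import annotations

import datetime as dt
import logging
import re
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

from .excel_dates import DisplayDate
from .months import ENGLISH, MonthTable

logger = logging.getLogger(__name__)

__all__ = [
    "ConversionResult",
    "simulate",
    "screen_gene_list",
    "count_by_taxon",
    "evaluate_name_arithmetic",
]

_MONTH_FIRST_RE = re.compile(r"^([^\W\d_]+)[-/. ]?(\d{1,4})$")
_NUMBER_FIRST_RE = re.compile(r"^(\d{1,2})[-/. ]?([^\W\d_]+)$")
_SCIENTIFIC_RE = re.compile(r"^(\d+)[eE](\d+)$")
_NAME_ARITH_RE = re.compile(r"^([^\W\d_]+)-(\d{1,3})$")

#: Logged-only oddities (numeric coercions the source data showed but whose
#: mechanism is unexplained); simulated only when experimental=True.
_EXPERIMENTAL_NUMERIC = {"inf2": "3002"}


@dataclass(frozen=True)
class ConversionResult:
    """Outcome of simulated autoconversion of one input string."""

    outcome: str  # unchanged | date | scientific | numeric
    display: str
    parsed: Union[DisplayDate, float, None] = None

    @property
    def converted(self) -> bool:
        return self.outcome != "unchanged"


def _match_month_number(
    text: str, tables: Sequence[MonthTable]
) -> Optional[tuple[int, int, bool]]:
    """Return (month, number, month_first) for a month-token + number string."""
    matches: list[tuple[int, int, bool, str]] = []
    match = _MONTH_FIRST_RE.match(text)
    if match:
        token, digits = match.group(1), match.group(2)
        for table in tables:
            month = table.lookup(token)
            if month is not None:
                matches.append((month, int(digits), True, table.locale_tag))
    match = _NUMBER_FIRST_RE.match(text)
    if match:
        digits, token = match.group(1), match.group(2)
        for table in tables:
            month = table.lookup(token)
            if month is not None:
                matches.append((month, int(digits), False, table.locale_tag))
    if not matches:
        return None
    if len({m[0] for m in matches}) > 1:
        logger.info(
            "month-token tie for %r across tables %s; first table wins",
            text,
            [m[3] for m in matches],
        )
    month, number, month_first, _ = matches[0]
    return month, number, month_first


def simulate(
    text: str,
    tables: Sequence[MonthTable] = (ENGLISH,),
    *,
    render: str = "d-mmm",
    year_pivot: int = 30,
    experimental: bool = False,
) -> ConversionResult:
    """Simulate what a date-converting spreadsheet does to *text*.

    Rules, applied in order:

    1. month token (optionally separated by ``-``, ``/``, ``.`` or space)
       joined to an integer n: n in 1-31 is a day-of-month (displayed
       ``7-Sep`` or ``Sep-07`` depending on *render*), n in 32-99 a
       two-digit year (displayed ``Jan-41``); number-then-month likewise.
       n = 0 or n ≥ 100 leaves the string alone.
    2. digits + E/e + digits parses as a scientific-notation float.
    3. anything else is unchanged.

    *render* selects day-date display: ``d-mmm`` (unpadded day first) or
    ``mmm-d`` (month first, zero-padded day).
    """
    text = text.strip()
    if not text:
        return ConversionResult("unchanged", text)

    hit = _match_month_number(text, tables)
    if hit is not None:
        month, number, _ = hit
        if 1 <= number <= 31:
            date = DisplayDate(
                month=month,
                day=number,
                source_format="mmm-d" if render == "mmm-d" else "d-mmm",
            )
            return ConversionResult("date", date.render(), date)
        if 32 <= number <= 99:
            year = 2000 + number if number < year_pivot else 1900 + number
            date = DisplayDate(month=month, year=year, source_format="mmm-yy")
            return ConversionResult("date", date.render(), date)

    match = _SCIENTIFIC_RE.match(text)
    if match:
        value = float(f"{match.group(1)}e{match.group(2)}")
        return ConversionResult("scientific", f"{value:E}", value)

    if text.casefold() in _EXPERIMENTAL_NUMERIC:
        if experimental:
            rendered = _EXPERIMENTAL_NUMERIC[text.casefold()]
            return ConversionResult("numeric", rendered, float(rendered))
        logger.info("known numeric-coercion pattern left unchanged: %r", text)

    return ConversionResult("unchanged", text)


def screen_gene_list(
    names: Iterable[str],
    tables: Sequence[MonthTable] = (ENGLISH,),
    **simulate_kwargs,
) -> list[tuple[str, ConversionResult]]:
    """Return the (name, result) pairs whose simulated outcome is a conversion.

    Input order is preserved; unconverted names are dropped.
    """
    out: list[tuple[str, ConversionResult]] = []
    for name in names:
        result = simulate(name, tables, **simulate_kwargs)
        if result.converted:
            out.append((name, result))
    return out


def count_by_taxon(
    labelled_names: Iterable[tuple[str, str]],
    tables: Sequence[MonthTable] = (ENGLISH,),
    **simulate_kwargs,
) -> Counter:
    """Count converted names per taxon over (taxon, name) pairs."""
    counts: Counter = Counter()
    for taxon, name in labelled_names:
        if simulate(name, tables, **simulate_kwargs).converted:
            counts[taxon] += 1
    return counts


def evaluate_name_arithmetic(
    text: str,
    tables: Sequence[MonthTable] = (ENGLISH,),
    *,
    year: int = 2001,
) -> Optional[DisplayDate]:
    """Evaluate ``token-n`` as the first of the token's month minus n days.

    Models the formula-evaluation failure mode in which a protein name like
    ``jun-1`` is read as June minus one day, yielding May-31.  The reference
    *year* (default 2001, a non-leap year) fixes the February length for
    subtractions crossing month boundaries.  Returns None on no match.
    """
    match = _NAME_ARITH_RE.match(text.strip())
    if match is None:
        return None
    month = None
    for table in tables:
        month = table.lookup(match.group(1))
        if month is not None:
            break
    if month is None:
        return None
    result = dt.date(year, month, 1) - dt.timedelta(days=int(match.group(2)))
    return DisplayDate(month=result.month, day=result.day, source_format="mmm-d")
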