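"""Reverse-map flagged cells to candidate gene symbols.

Repairs are suggestions, never applied in place: silent modification is the
root problem being detected.  For date-shaped records, every month token
mapping to the decoded month is concatenated with the day (padded and
unpadded) or two-digit year, and the fabrications are filtered away by
dictionary membership.  Five-digit serials are first decoded to a calendar
date.  Scientific records are inverted by exact float equality against the
dictionary's mantissa+exponent-shaped symbols.
"""

from __future__ import annotations

import datetime as dt
import re
from dataclasses import dataclass, field
from typing import Sequence

from .excel_dates import DisplayDate
from .gene_dictionary import GeneDictionary
from .months import BUILTIN_TABLES, MonthTable
from .scanner import ErrorRecord, ScanReport

__all__ = ["candidates_for", "suggest_fixes", "RepairSummary"]

_SCI_SYMBOL_RE = re.compile(r"^\d+[eE]\d+$")


def _date_parts(record: ErrorRecord) -> tuple[int | None, int | None, int | None]:
    """(month, day, two-digit year) decoded from a record, or Nones."""
    decoded = record.decoded
    if isinstance(decoded, DisplayDate):
        year = decoded.year % 100 if decoded.year is not None else None
        return decoded.month, decoded.day, year
    if isinstance(decoded, dt.date):
        return decoded.month, decoded.day, decoded.year % 100
    return None, None, None


def candidates_for(
    record: ErrorRecord,
    dictionary: GeneDictionary,
    tables: Sequence[MonthTable] = BUILTIN_TABLES,
) -> list[str]:
    """Dictionary symbols that autoconversion could have turned into *record*.

    Candidates are ordered most-specific (longest) first; modernized names
    from the dictionary's rename table are appended after their vulnerable
    originals.  Undecodable records yield an empty list.
    """
    base: list[str] = []
    seen: set[str] = set()

    if record.error_class == "scientific" and isinstance(record.decoded, float):
        for norm in sorted(dictionary.symbols):
            original = dictionary.original(norm)
            if _SCI_SYMBOL_RE.match(original) and float(original) == record.decoded:
                base.append(original)
                seen.add(norm)
    else:
        month, day, year2 = _date_parts(record)
        if month is None:
            return []
        numbers: list[str] = []
        if day is not None:
            numbers += [str(day), f"{day:02d}"]
        if year2 is not None:
            numbers += [str(year2), f"{year2:02d}"]
        tokens: list[str] = []
        for table in tables:
            for token in table.tokens_for(month):
                if token not in tokens:
                    tokens.append(token)
        for token in tokens:
            for number in numbers:
                norm = f"{token}{number}".casefold()
                if norm in dictionary.symbols and norm not in seen:
                    seen.add(norm)
                    base.append(dictionary.original(norm))
        base.sort(key=lambda s: (-len(s), s))

    modern = [
        dictionary.modern_name(symbol)
        for symbol in base
        if dictionary.modern_name(symbol)
    ]
    return base + [m for m in modern if m is not None]


@dataclass
class RepairSummary:
    """Counts of how decisively flagged records could be reverse-mapped."""

    unambiguous: int = 0
    ambiguous: int = 0
    unresolvable: int = 0
    n_base_candidates: dict[int, int] = field(default_factory=dict)


def suggest_fixes(
    report: ScanReport,
    dictionary: GeneDictionary,
    tables: Sequence[MonthTable] = BUILTIN_TABLES,
) -> RepairSummary:
    """Fill the candidates of every record in *report*; return counts.

    Ambiguity is judged on dictionary candidates only (rename images are
    appended extras, not alternatives).
    """
    summary = RepairSummary()
    for record in report.records:
        candidates = candidates_for(record, dictionary, tables)
        record.candidates = candidates
        n_base = sum(
            1 for c in candidates if c.casefold() in dictionary.symbols
        )
        summary.n_base_candidates[n_base] = summary.n_base_candidates.get(n_base, 0) + 1
        if n_base == 0:
            summary.unresolvable += 1
        elif n_base == 1:
            summary.unambiguous += 1
        else:
            summary.ambiguous += 1
    return summary
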