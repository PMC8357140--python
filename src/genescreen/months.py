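"""Locale month-token tables used for autoconversion simulation and date parsing.

A :class:`MonthTable` maps lowercase month tokens (full names, abbreviations
and truncations accepted by spreadsheet software) to month numbers 1-12.
Tables for the locales known to corrupt gene symbols are built in; arbitrary
tables can be loaded from a three-column TSV (locale_tag, token, month).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "MonthTable",
    "ENGLISH",
    "ITALIAN_SPANISH_PORTUGUESE",
    "DUTCH",
    "FINNISH",
    "BUILTIN_TABLES",
    "MONTH_ABBREV",
    "month_abbrev",
    "load_month_tables",
    "builtin_table",
]

#: English three-letter abbreviations used for rendering display dates.
MONTH_ABBREV = (
    "Jan", "Feb", "Mar", "Apr", "May", "Jun",
    "Jul", "Aug", "Sep", "Oct", "Nov", "Dec",
)


def month_abbrev(month: int) -> str:
    """Return the capitalized English three-letter abbreviation for *month*."""
    return MONTH_ABBREV[month - 1]


@dataclass(frozen=True)
class MonthTable:
    """Case-insensitive mapping from month tokens to month numbers."""

    locale_tag: str
    tokens: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lowered: dict[str, int] = {}
        for token, month in self.tokens.items():
            key = token.casefold()
            if not key:
                raise ValueError("empty month token")
            if not 1 <= month <= 12:
                raise ValueError(f"month out of range for token {token!r}: {month}")
            if key in lowered and lowered[key] != month:
                raise ValueError(f"conflicting month for token {token!r}")
            lowered[key] = month
        object.__setattr__(self, "tokens", lowered)

    def lookup(self, token: str) -> int | None:
        """Month number for *token* (case-insensitive), or None."""
        return self.tokens.get(token.casefold())

    def tokens_for(self, month: int) -> list[str]:
        """All tokens of this table mapping to *month*, longest first."""
        hits = [t for t, m in self.tokens.items() if m == month]
        return sorted(hits, key=lambda t: (-len(t), t))


def _table(tag: str, names: Iterable[tuple[str, int]]) -> MonthTable:
    return MonthTable(tag, dict(names))


_EN_FULL = (
    "january", "february", "march", "april", "may", "june",
    "july", "august", "september", "october", "november", "december",
)

ENGLISH = _table(
    "en",
    [(name, i + 1) for i, name in enumerate(_EN_FULL)]
    + [(name[:3], i + 1) for i, name in enumerate(_EN_FULL)]
    + [("sept", 9)],
)

# Combined table for the Romance locales whose shared "ago" token (agosto)
# converts AGO2 to an August date.
ITALIAN_SPANISH_PORTUGUESE = _table(
    "it-es-pt",
    [
        ("gennaio", 1), ("febbraio", 2), ("marzo", 3), ("aprile", 4),
        ("maggio", 5), ("giugno", 6), ("luglio", 7), ("agosto", 8),
        ("settembre", 9), ("ottobre", 10), ("novembre", 11), ("dicembre", 12),
        ("enero", 1), ("febrero", 2), ("abril", 4), ("mayo", 5),
        ("junio", 6), ("julio", 7), ("septiembre", 9), ("octubre", 10),
        ("noviembre", 11), ("diciembre", 12),
        ("janeiro", 1), ("fevereiro", 2), ("marco", 3), ("março", 3),
        ("maio", 5), ("junho", 6), ("julho", 7), ("setembro", 9),
        ("outubro", 10), ("novembro", 11), ("dezembro", 12),
        ("gen", 1), ("ene", 1), ("fev", 2), ("feb", 2), ("mar", 3),
        ("abr", 4), ("mag", 5), ("mai", 5), ("giu", 6), ("lug", 7),
        ("ago", 8), ("set", 9), ("ott", 10), ("out", 10), ("nov", 11),
        ("dic", 12), ("dez", 12),
    ],
)

DUTCH = _table(
    "nl",
    [
        ("januari", 1), ("februari", 2), ("maart", 3), ("april", 4),
        ("mei", 5), ("juni", 6), ("juli", 7), ("augustus", 8),
        ("september", 9), ("oktober", 10), ("november", 11), ("december", 12),
        ("jan", 1), ("feb", 2), ("mrt", 3), ("apr", 4), ("jun", 6),
        ("jul", 7), ("aug", 8), ("sep", 9), ("okt", 10), ("nov", 11),
        ("dec", 12),
    ],
)

# "tamm" is included because truncated tokens of tammikuu (January) are
# accepted by spreadsheet software, turning TAMM41 into Jan-41.
FINNISH = _table(
    "fi",
    [
        ("tammikuu", 1), ("helmikuu", 2), ("maaliskuu", 3), ("huhtikuu", 4),
        ("toukokuu", 5), ("kesäkuu", 6), ("heinäkuu", 7), ("elokuu", 8),
        ("syyskuu", 9), ("lokakuu", 10), ("marraskuu", 11), ("joulukuu", 12),
        ("tammi", 1), ("helmi", 2), ("maalis", 3), ("huhti", 4),
        ("touko", 5), ("kesä", 6), ("heinä", 7), ("elo", 8),
        ("syys", 9), ("loka", 10), ("marras", 11), ("joulu", 12),
        ("tamm", 1),
    ],
)

BUILTIN_TABLES: tuple[MonthTable, ...] = (
    ENGLISH,
    ITALIAN_SPANISH_PORTUGUESE,
    DUTCH,
    FINNISH,
)


def builtin_table(tag: str) -> MonthTable:
    """Return the builtin table with locale tag *tag*."""
    for table in BUILTIN_TABLES:
        if table.locale_tag == tag:
            return table
    raise KeyError(f"no builtin month table with tag {tag!r}")


def load_month_tables(path: str | Path) -> list[MonthTable]:
    """Load month tables from a TSV with columns locale_tag, token, month."""
    grouped: dict[str, dict[str, int]] = {}
    order: list[str] = []
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.reader(handle, delimiter="\t")
        for row in reader:
            if not row or row[0].startswith("#"):
                continue
            if len(row) != 3:
                raise ValueError(f"expected 3 columns in month table row: {row!r}")
            tag, token, month = row[0].strip(), row[1].strip(), int(row[2])
            if tag not in grouped:
                grouped[tag] = {}
                order.append(tag)
            grouped[tag][token] = month
    return [MonthTable(tag, grouped[tag]) for tag in order]
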