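"""Core screen: find gene-symbol columns and flag autoconversion damage.

The screen is two-stage, mirroring the detect-then-classify design: columns
with at least five intact gene symbols qualify as gene lists, and only
cells inside qualifying columns are classified.  Flagged classes are the
display date shapes (d-mmm, mmm-d, mmm-yy, slash, ISO), scientific
notation, and five-digit numbers decoding to internal date serials.
"""

from __future__ import annotations

import datetime as dt
import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

from .excel_dates import (
    DEFAULT_SERIAL_WINDOW,
    DateDialect,
    DisplayDate,
    InvalidSerialError,
    is_candidate_serial,
    serial_to_date,
)
from .gene_dictionary import GeneDictionary
from .spreadsheet_io import (
    FileType,
    SpreadsheetError,
    Table,
    UnsupportedFormatError,
    read_tables,
    sniff_file_type,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ERROR_CLASSES",
    "ScanConfig",
    "ErrorRecord",
    "ScanReport",
    "PublicationStats",
    "PublicationRollup",
    "GroupingError",
    "detect_gene_columns",
    "classify_cell",
    "scan_table",
    "scan_file",
    "combine_reports",
    "rollup_publications",
]

ERROR_CLASSES = (
    "d-mmm",
    "mmm-d",
    "mmm-yy",
    "slash-date",
    "iso-date",
    "scientific",
    "five-digit-serial",
)

_FORMAT_TO_CLASS = {
    "d-mmm": "d-mmm",
    "mmm-d": "mmm-d",
    "mmm-yy": "mmm-yy",
    "slash": "slash-date",
    "iso": "iso-date",
}

_SCIENTIFIC_RE = re.compile(r"^\d+(\.\d+)?[eE][+-]?\d+$")
# Leading zeros excluded: a spreadsheet would render serial 04321 as 4321.
_FIVE_DIGIT_RE = re.compile(r"^[1-9]\d{4}$")


@dataclass(frozen=True)
class ScanConfig:
    """Knobs for the screen; defaults mirror the published methodology."""

    min_hits: int = 5
    dialect: DateDialect = DateDialect()
    serial_window: tuple[int, int] = DEFAULT_SERIAL_WINDOW
    scan_transposed: bool = False
    context_cells: int = 3


DEFAULT_CONFIG = ScanConfig()


@dataclass
class ErrorRecord:
    """One flagged cell."""

    file: str
    sheet: str
    column: int
    row: int
    raw: str
    error_class: str
    decoded: Union[DisplayDate, dt.date, float, None] = None
    candidates: list[str] = field(default_factory=list)
    context: list[str] = field(default_factory=list)

    def decoded_text(self) -> str:
        if isinstance(self.decoded, DisplayDate):
            return self.decoded.render()
        if isinstance(self.decoded, dt.date):
            return self.decoded.isoformat()
        if self.decoded is None:
            return ""
        return repr(self.decoded)


@dataclass
class ScanReport:
    """Per-file (or combined) rollup of flagged cells."""

    files_screened: int = 0
    files_with_gene_lists: int = 0
    files_affected: int = 0
    records: list[ErrorRecord] = field(default_factory=list)
    skipped: list[str] = field(default_factory=list)
    path: Optional[str] = None

    @property
    def per_class_counts(self) -> Counter:
        return Counter(record.error_class for record in self.records)

    @property
    def affected(self) -> bool:
        return bool(self.records)

    def validate(self) -> None:
        assert self.files_affected <= self.files_with_gene_lists <= self.files_screened
        assert sum(self.per_class_counts.values()) == len(self.records)


def detect_gene_columns(
    table: Table,
    dictionary: GeneDictionary,
    min_hits: int = 5,
) -> list[int]:
    """Indices of columns holding *min_hits* or more intact gene symbols.

    Only intact symbols count toward the threshold — converted cells do
    not — so a short fully-converted column is not detectable (known
    limitation of the two-stage design).
    """
    out = []
    for index in range(table.n_cols):
        hits = sum(1 for cell in table.column(index) if dictionary.is_symbol(cell))
        if hits >= min_hits:
            out.append(index)
    return out


def classify_cell(
    raw: str,
    serial_tag: Optional[int] = None,
    config: ScanConfig = DEFAULT_CONFIG,
    dictionary: Optional[GeneDictionary] = None,
) -> Optional[tuple[str, Union[DisplayDate, dt.date, float, None]]]:
    """Classify one gene-column cell; returns (error_class, decoded) or None.

    Intact dictionary symbols are never flagged.  A five-digit token inside
    the plausibility window decodes via serial arithmetic; a date-typed
    cell (serial_tag) is flagged whatever its display format.
    """
    raw = raw.strip()
    if not raw:
        return None
    if dictionary is not None and dictionary.is_symbol(raw):
        return None

    display = None
    try:
        display = _parse(raw, config.dialect)
    except ValueError:
        display = None
    if display is not None:
        decoded: Union[DisplayDate, dt.date] = display
        if serial_tag is not None:
            try:
                decoded = serial_to_date(serial_tag)
            except InvalidSerialError:
                pass
        return _FORMAT_TO_CLASS[display.source_format], decoded

    if _SCIENTIFIC_RE.match(raw):
        return "scientific", float(raw)

    if _FIVE_DIGIT_RE.match(raw) and is_candidate_serial(int(raw), config.serial_window):
        try:
            return "five-digit-serial", serial_to_date(int(raw))
        except InvalidSerialError:
            return None

    if serial_tag is not None:
        # True date cell in an unrecognized display format: still flag it.
        try:
            date = serial_to_date(serial_tag)
        except InvalidSerialError:
            return None
        if is_candidate_serial(serial_tag, config.serial_window):
            return "five-digit-serial", date
        return "iso-date", date

    return None


def _parse(raw: str, dialect: DateDialect) -> Optional[DisplayDate]:
    from .excel_dates import parse_display_date

    return parse_display_date(raw, dialect)


def scan_table(
    table: Table,
    dictionary: GeneDictionary,
    config: ScanConfig = DEFAULT_CONFIG,
) -> list[ErrorRecord]:
    """Flag suspect cells inside the gene columns of one table."""
    records: list[ErrorRecord] = []
    columns = detect_gene_columns(table, dictionary, config.min_hits)
    for col in columns:
        cells = table.column(col)
        for row, raw in enumerate(cells):
            serial_tag = table.serials[row][col]
            hit = classify_cell(raw, serial_tag, config, dictionary)
            if hit is None:
                continue
            error_class, decoded = hit
            records.append(
                ErrorRecord(
                    file=table.source_path,
                    sheet=table.sheet_name,
                    column=col,
                    row=row,
                    raw=raw,
                    error_class=error_class,
                    decoded=decoded,
                    context=_context(cells, row, config.context_cells),
                )
            )
    if config.scan_transposed:
        records.extend(_scan_transposed(table, dictionary, config))
    return records


def _context(cells: Sequence[str], row: int, n: int) -> list[str]:
    """Up to *n* neighbouring cells (one above, the rest below) for review."""
    out = []
    if row > 0:
        out.append(cells[row - 1])
    out.extend(cells[row + 1 : row + n])
    return out[:n]


def _scan_transposed(
    table: Table, dictionary: GeneDictionary, config: ScanConfig
) -> list[ErrorRecord]:
    transposed = Table(
        table.source_path,
        table.sheet_name + ":transposed",
        [list(row) for row in zip(*table.cells)] if table.cells else [],
        [list(row) for row in zip(*table.serials)] if table.serials else [],
    )
    flipped_config = ScanConfig(
        min_hits=config.min_hits,
        dialect=config.dialect,
        serial_window=config.serial_window,
        scan_transposed=False,
        context_cells=config.context_cells,
    )
    records = scan_table(transposed, dictionary, flipped_config)
    for record in records:
        record.row, record.column = record.column, record.row
        record.sheet = table.sheet_name
    return records


def scan_file(
    path: Union[str, Path],
    dictionary: GeneDictionary,
    config: ScanConfig = DEFAULT_CONFIG,
) -> ScanReport:
    """Sniff, read and screen one file; unreadable files are logged skips."""
    path = Path(path)
    report = ScanReport(files_screened=1, path=str(path))
    try:
        kind = sniff_file_type(path)
        if kind is FileType.UNKNOWN:
            raise SpreadsheetError(f"unknown file type: {path}")
        tables = read_tables(path)
    except UnsupportedFormatError as exc:
        logger.warning("skipping %s: %s", path, exc)
        report.skipped.append(str(path))
        return report
    except SpreadsheetError as exc:
        logger.warning("skipping %s: %s", path, exc)
        report.skipped.append(str(path))
        return report
    has_gene_list = False
    for table in tables:
        if detect_gene_columns(table, dictionary, config.min_hits):
            has_gene_list = True
        elif config.scan_transposed and table.cells:
            flipped = Table(
                table.source_path,
                table.sheet_name,
                [list(row) for row in zip(*table.cells)],
            )
            if detect_gene_columns(flipped, dictionary, config.min_hits):
                has_gene_list = True
        report.records.extend(scan_table(table, dictionary, config))
    report.files_with_gene_lists = int(has_gene_list)
    report.files_affected = int(bool(report.records))
    report.validate()
    return report


def combine_reports(reports: Sequence[ScanReport]) -> ScanReport:
    """Sum per-file reports into one corpus-level report."""
    out = ScanReport()
    for report in reports:
        out.files_screened += report.files_screened
        out.files_with_gene_lists += report.files_with_gene_lists
        out.files_affected += report.files_affected
        out.records.extend(report.records)
        out.skipped.extend(report.skipped)
    out.validate()
    return out


class GroupingError(KeyError):
    """A scanned file has no publication mapping."""


@dataclass
class PublicationStats:
    files_screened: int = 0
    files_with_gene_lists: int = 0
    files_affected: int = 0
    n_records: int = 0

    @property
    def affected(self) -> bool:
        return self.files_affected > 0

    @property
    def has_gene_list(self) -> bool:
        return self.files_with_gene_lists > 0


@dataclass
class PublicationRollup:
    per_publication: dict[str, PublicationStats]

    @property
    def publications_screened(self) -> int:
        return len(self.per_publication)

    @property
    def publications_with_gene_lists(self) -> int:
        return sum(1 for s in self.per_publication.values() if s.has_gene_list)

    @property
    def publications_affected(self) -> int:
        return sum(1 for s in self.per_publication.values() if s.affected)

    @property
    def affected_files(self) -> int:
        return sum(s.files_affected for s in self.per_publication.values())


def rollup_publications(
    reports: Sequence[ScanReport],
    grouping: Mapping[str, str],
) -> PublicationRollup:
    """Aggregate per-file reports to publications.

    *grouping* maps each scanned file path to a publication id; a missing
    mapping raises :class:`GroupingError`.  A publication is affected iff
    at least one of its files is affected.
    """
    per_pub: dict[str, PublicationStats] = {}
    for report in reports:
        if report.path is None:
            raise GroupingError("combined report passed where per-file expected")
        if report.path not in grouping:
            raise GroupingError(f"no publication mapping for {report.path}")
        stats = per_pub.setdefault(grouping[report.path], PublicationStats())
        stats.files_screened += report.files_screened
        stats.files_with_gene_lists += report.files_with_gene_lists
        stats.files_affected += report.files_affected
        stats.n_records += len(report.records)
    return PublicationRollup(per_pub)
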