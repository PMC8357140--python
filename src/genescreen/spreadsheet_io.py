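"""Read spreadsheets and delimited files into rectangular string tables.

File type is sniffed from content (ZIP magic → xlsx, OLE compound magic →
xls, line-oriented text → delimited); suffixes are never trusted, because a
notable share of supplementary ".xls" files are really TSVs.  Cell values
are surfaced as display strings without silent re-typing; date-typed cells
additionally carry their underlying day serial so the scanner can flag them
regardless of display format.
"""

from __future__ import annotations

import csv
import datetime as dt
import io
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional, Union

from .excel_dates import DateOutOfRangeError, date_to_serial
from .months import month_abbrev

logger = logging.getLogger(__name__)

__all__ = [
    "FileType",
    "Table",
    "SpreadsheetError",
    "UnsupportedFormatError",
    "sniff_file_type",
    "read_tables",
    "write_tsv",
]

_ZIP_MAGIC = b"PK\x03\x04"
_OLE_MAGIC = b"\xd0\xcf\x11\xe0\xa1\xb1\x1a\xe1"


class FileType(str, Enum):
    XLSX = "xlsx"
    XLS = "xls"
    DELIMITED = "delimited-text"
    UNKNOWN = "unknown"


class SpreadsheetError(Exception):
    """Problem reading a spreadsheet or delimited file."""


class UnsupportedFormatError(SpreadsheetError):
    """File format recognized but no reader is available."""


@dataclass
class Table:
    """A rectangular grid of raw cell strings from one sheet.

    ``serials[r][c]`` holds the underlying 1900-system day serial for cells
    that were stored as true dates, else None.
    """

    source_path: str
    sheet_name: str
    cells: list[list[str]]
    serials: list[list[Optional[int]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        width = max((len(row) for row in self.cells), default=0)
        for row in self.cells:
            row.extend([""] * (width - len(row)))
        if not self.serials:
            self.serials = [[None] * width for _ in self.cells]
        else:
            for row in self.serials:
                row.extend([None] * (width - len(row)))

    @property
    def n_rows(self) -> int:
        return len(self.cells)

    @property
    def n_cols(self) -> int:
        return len(self.cells[0]) if self.cells else 0

    def column(self, index: int) -> list[str]:
        return [row[index] for row in self.cells]


def sniff_file_type(path: Union[str, Path]) -> FileType:
    """Classify a file by magic bytes and content, ignoring its suffix."""
    path = Path(path)
    try:
        with open(path, "rb") as handle:
            head = handle.read(8)
            body = head + handle.read(65536)
    except OSError as exc:
        raise SpreadsheetError(f"cannot read {path}: {exc}") from exc
    if head.startswith(_ZIP_MAGIC):
        return FileType.XLSX
    if head.startswith(_OLE_MAGIC):
        return FileType.XLS
    if not body:
        return FileType.UNKNOWN
    if b"\x00" in body:
        return FileType.UNKNOWN
    try:
        body.decode("utf-8")
    except UnicodeDecodeError:
        try:
            body.decode("latin-1")
        except UnicodeDecodeError:
            return FileType.UNKNOWN
    return FileType.DELIMITED


def read_tables(path: Union[str, Path]) -> list[Table]:
    """Read every sheet of *path* into a :class:`Table`.

    Numeric cells render preserving integer-ness (``43709``, never
    ``43709.0``); date cells render per their number format and carry their
    serial.  Raises :class:`UnsupportedFormatError` for OLE ``.xls`` input
    (no reader in this environment) and :class:`SpreadsheetError` for
    unknown or corrupt content.
    """
    path = Path(path)
    kind = sniff_file_type(path)
    if kind is FileType.XLSX:
        return _read_xlsx(path)
    if kind is FileType.XLS:
        try:
            import xlrd  # noqa: F401  optional, usually absent
        except ImportError:
            raise UnsupportedFormatError(
                f"{path} is an OLE .xls workbook; install xlrd to read it"
            ) from None
        return _read_xls(path)
    if kind is FileType.DELIMITED:
        return [_read_delimited(path)]
    raise SpreadsheetError(f"unrecognized file content: {path}")


def _render_number(value: float) -> str:
    if value == int(value) and abs(value) < 1e16:
        return str(int(value))
    return repr(value)


_DATE_FORMATS = {
    "d-mmm": lambda d: f"{d.day}-{month_abbrev(d.month)}",
    "dd-mmm": lambda d: f"{d.day:02d}-{month_abbrev(d.month)}",
    "mmm-d": lambda d: f"{month_abbrev(d.month)}-{d.day}",
    "mmm-dd": lambda d: f"{month_abbrev(d.month)}-{d.day:02d}",
    "mmm-yy": lambda d: f"{month_abbrev(d.month)}-{d.year % 100:02d}",
    "m/d/yyyy": lambda d: f"{d.month}/{d.day}/{d.year}",
    "d/m/yyyy": lambda d: f"{d.day}/{d.month}/{d.year}",
    "dd/mm/yyyy": lambda d: f"{d.day:02d}/{d.month:02d}/{d.year}",
    "yyyy-mm-dd": lambda d: f"{d.year:04d}-{d.month:02d}-{d.day:02d}",
}


def _render_date(value: dt.date, number_format: str) -> str:
    fmt = number_format.split(";")[0].strip().lower()
    renderer = _DATE_FORMATS.get(fmt)
    if renderer is None:
        return f"{value.year:04d}-{value.month:02d}-{value.day:02d}"
    return renderer(value)


def _read_xlsx(path: Path) -> list[Table]:
    from openpyxl import load_workbook
    from openpyxl.utils.exceptions import InvalidFileException

    try:
        workbook = load_workbook(path, data_only=True, read_only=False)
    except (InvalidFileException, OSError, KeyError, ValueError) as exc:
        raise SpreadsheetError(f"cannot parse xlsx {path}: {exc}") from exc
    tables: list[Table] = []
    for sheet in workbook.worksheets:
        cells: list[list[str]] = []
        serials: list[list[Optional[int]]] = []
        try:
            for row in sheet.iter_rows():
                texts: list[str] = []
                tags: list[Optional[int]] = []
                for cell in row:
                    text, serial = _render_cell(cell)
                    texts.append(text)
                    tags.append(serial)
                cells.append(texts)
                serials.append(tags)
        except Exception as exc:  # corrupt archive member
            raise SpreadsheetError(
                f"corrupt sheet {sheet.title!r} in {path}: {exc}"
            ) from exc
        tables.append(Table(str(path), sheet.title, cells, serials))
    workbook.close()
    return tables


def _render_cell(cell) -> tuple[str, Optional[int]]:
    value = cell.value
    if value is None:
        return "", None
    if isinstance(value, str):
        return value, None
    if isinstance(value, bool):
        return ("TRUE" if value else "FALSE"), None
    if isinstance(value, (dt.datetime, dt.date)):
        date = value.date() if isinstance(value, dt.datetime) else value
        try:
            serial = date_to_serial(date)
        except DateOutOfRangeError:
            serial = None
        return _render_date(date, cell.number_format or ""), serial
    if isinstance(value, int):
        return str(value), None
    if isinstance(value, float):
        return _render_number(value), None
    return str(value), None


def _read_xls(path: Path) -> list[Table]:  # pragma: no cover - needs xlrd
    import xlrd

    book = xlrd.open_workbook(str(path))
    tables = []
    for sheet in book.sheets():
        cells = [
            [_render_xls_value(sheet.cell(r, c), book.datemode) for c in range(sheet.ncols)]
            for r in range(sheet.nrows)
        ]
        tables.append(Table(str(path), sheet.name, [[t for t, _ in row] for row in cells],
                            [[s for _, s in row] for row in cells]))
    return tables


def _render_xls_value(cell, datemode) -> tuple[str, Optional[int]]:  # pragma: no cover
    import xlrd

    if cell.ctype == xlrd.XL_CELL_DATE:
        date = dt.datetime(*xlrd.xldate_as_tuple(cell.value, datemode)).date()
        return f"{date:%Y-%m-%d}", date_to_serial(date)
    if cell.ctype == xlrd.XL_CELL_NUMBER:
        return _render_number(cell.value), None
    if cell.ctype == xlrd.XL_CELL_EMPTY:
        return "", None
    return str(cell.value), None


def _read_delimited(path: Path) -> Table:
    raw = path.read_bytes()
    try:
        text = raw.decode("utf-8")
    except UnicodeDecodeError:
        logger.info("falling back to latin-1 for %s", path)
        text = raw.decode("latin-1")
    delimiter = _detect_delimiter(text)
    rows = list(csv.reader(io.StringIO(text), delimiter=delimiter))
    rows = [row for row in rows] or [[]]
    return Table(str(path), path.stem, rows)


def _detect_delimiter(text: str) -> str:
    """Try tab then comma; prefer the one giving a consistent column count."""
    lines = [line for line in text.splitlines() if line.strip()]
    best = None
    for delimiter in ("\t", ","):
        counts = {len(row) for row in csv.reader(lines, delimiter=delimiter)}
        if counts and counts != {1}:
            if len(counts) == 1:
                logger.debug("delimiter %r gives consistent width", delimiter)
                return delimiter
            if best is None:
                best = delimiter
    return best or "\t"


def write_tsv(table: Table, path: Union[str, Path]) -> None:
    """Write a table to TSV (mirrors the extract-to-tabular step)."""
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t")
        writer.writerows(table.cells)
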