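"""Gene-symbol dictionaries: loading, normalization and membership tests.

The dictionary is fully pluggable — any delimited symbol list or GTF
annotation can back it.  A small bundled fixture dictionary (a few hundred
symbols mixing autoconversion-vulnerable and safe names, plus the
SEPT→SEPTIN / MARCH→MARCHF renaming pairs) keeps the package usable with no
downloads.

Normalization trims whitespace, strips surrounding quotes and case-folds.
Hyphens and dots are preserved so that protein names like ``jun-1`` stay
distinct from the gene ``JUN1``.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

logger = logging.getLogger(__name__)

__all__ = [
    "DictionaryLoadError",
    "EmptyDictionaryError",
    "EmptyExtractionError",
    "GeneDictionary",
    "normalize_symbol",
    "load_symbols",
    "load_renames",
    "extract_names_from_gtf",
    "bundled_dictionary",
]


class DictionaryLoadError(ValueError):
    """Missing file or column while loading a symbol set."""


class EmptyDictionaryError(DictionaryLoadError):
    """A symbol source yielded zero symbols."""


class EmptyExtractionError(DictionaryLoadError):
    """A GTF carried no gene_name attributes."""


_QUOTES = "\"'"


def normalize_symbol(text: str) -> str:
    """Trim, strip surrounding quotes and case-fold; idempotent."""
    out = text
    while True:
        stripped = out.strip().strip(_QUOTES)
        if stripped == out:
            break
        out = stripped
    return out.casefold()


@dataclass
class GeneDictionary:
    """Normalized gene-symbol set with optional old→new renaming pairs."""

    symbols: set[str] = field(default_factory=set)
    renames: dict[str, str] = field(default_factory=dict)
    species_label: str = ""
    #: first-seen original spelling per normalized symbol
    originals: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_symbols(
        cls,
        symbols: Iterable[str],
        renames: Optional[Mapping[str, str]] = None,
        species_label: str = "",
    ) -> "GeneDictionary":
        out = cls(species_label=species_label)
        for sym in symbols:
            out.add(sym)
        for old, new in (renames or {}).items():
            out.add_rename(old, new)
        return out

    def add(self, symbol: str) -> None:
        norm = normalize_symbol(symbol)
        if not norm:
            return
        self.symbols.add(norm)
        self.originals.setdefault(norm, symbol.strip().strip(_QUOTES))

    def add_rename(self, old: str, new: str) -> None:
        old_n, new_n = normalize_symbol(old), normalize_symbol(new)
        if not old_n or not new_n:
            raise DictionaryLoadError(f"empty symbol in rename pair {old!r}→{new!r}")
        self.renames[old_n] = new.strip().strip(_QUOTES)

    def is_symbol(self, cell: str) -> bool:
        """True iff the normalized cell is a known symbol."""
        if not cell:
            return False
        return normalize_symbol(cell) in self.symbols

    def __contains__(self, cell: str) -> bool:
        return self.is_symbol(cell)

    def __len__(self) -> int:
        return len(self.symbols)

    def original(self, symbol: str) -> str:
        """Canonical (first-seen) spelling for a symbol, if known."""
        return self.originals.get(normalize_symbol(symbol), symbol)

    def modern_name(self, symbol: str) -> Optional[str]:
        """Renamed modern symbol (e.g. SEPT1 → SEPTIN1), or None."""
        return self.renames.get(normalize_symbol(symbol))


def is_symbol(cell: str, dictionary: GeneDictionary) -> bool:
    """Functional alias for :meth:`GeneDictionary.is_symbol`."""
    return dictionary.is_symbol(cell)


def load_symbols(
    path: Union[str, Path],
    column: Union[str, int] = 0,
    species_label: str = "",
) -> GeneDictionary:
    """Load a symbol dictionary from a CSV/TSV file.

    *column* may be a 0-based index (file read headerless) or a header name
    (first row treated as the header).  Duplicate symbols collapse under
    normalization.
    """
    path = Path(path)
    if not path.is_file():
        raise DictionaryLoadError(f"symbol file not found: {path}")
    lines = _read_text(path).splitlines()
    delimiter = "\t" if lines and "\t" in lines[0] else ","
    rows = list(csv.reader(lines, delimiter=delimiter))
    rows = [row for row in rows if any(cell.strip() for cell in row)]
    if not rows:
        raise EmptyDictionaryError(f"no rows in {path}")
    if isinstance(column, str):
        header = [h.strip() for h in rows[0]]
        if column not in header:
            raise DictionaryLoadError(f"column {column!r} not in header of {path}")
        idx = header.index(column)
        data = rows[1:]
    else:
        idx = column
        data = rows
        # tolerate a header row when loading by index
        if data and idx < len(data[0]) and data[0][idx].strip().lower() in {
            "symbol", "gene", "gene_name", "name",
        }:
            data = data[1:]
    out = GeneDictionary(species_label=species_label)
    for row in data:
        if idx >= len(row):
            continue
        out.add(row[idx])
    if not out.symbols:
        raise EmptyDictionaryError(f"no symbols loaded from {path}")
    return out


def load_renames(path: Union[str, Path]) -> dict[str, str]:
    """Load old→new renaming pairs from a two-column TSV."""
    path = Path(path)
    if not path.is_file():
        raise DictionaryLoadError(f"rename file not found: {path}")
    pairs: dict[str, str] = {}
    with open(path, newline="", encoding="utf-8") as handle:
        for row in csv.reader(handle, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            if row[0].strip().lower() in {"old", "old_symbol"}:
                continue
            if len(row) < 2:
                raise DictionaryLoadError(f"rename row needs 2 columns: {row!r}")
            pairs[normalize_symbol(row[0])] = row[1].strip()
    return pairs


_GENE_NAME_RE = re.compile(r'gene_name\s+"([^"]*)"')


def extract_names_from_gtf(path: Union[str, Path]) -> list[str]:
    """Extract unique gene_name values from gene records of a GTF file.

    Returns original-case names, unique under normalization, in first-seen
    order.  Malformed lines are skipped with a logged count; a file with no
    gene_name attributes raises :class:`EmptyExtractionError`.
    """
    path = Path(path)
    if not path.is_file():
        raise DictionaryLoadError(f"GTF not found: {path}")
    names: list[str] = []
    seen: set[str] = set()
    malformed = 0
    with open(path, encoding="utf-8", errors="replace") as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                malformed += 1
                continue
            if fields[2] != "gene":
                continue
            match = _GENE_NAME_RE.search(fields[8])
            if not match or not match.group(1):
                continue
            norm = normalize_symbol(match.group(1))
            if norm not in seen:
                seen.add(norm)
                names.append(match.group(1))
    if malformed:
        logger.warning("skipped %d malformed GTF lines in %s", malformed, path)
    if not names:
        raise EmptyExtractionError(f"no gene_name attributes in {path}")
    return names


def _read_text(path: Path) -> str:
    raw = path.read_bytes()
    try:
        return raw.decode("utf-8")
    except UnicodeDecodeError:
        logger.info("falling back to latin-1 for %s", path)
        return raw.decode("latin-1")


def bundled_dictionary() -> GeneDictionary:
    """The bundled fixture dictionary with renaming pairs loaded."""
    data = resources.files("genescreen.data")
    with resources.as_file(data / "symbols.tsv") as sym_path:
        out = load_symbols(sym_path, column="symbol", species_label="fixture")
    with resources.as_file(data / "renames.tsv") as ren_path:
        for old, new in load_renames(ren_path).items():
            out.renames[old] = new
    return out
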