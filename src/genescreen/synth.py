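"""Synthetic corpora with ground-truth error manifests.

Generates publication directories of XLSX/TSV supplementary files whose
gene columns are drawn from a dictionary, corrupts vulnerable cells at a
configurable rate with a configurable class mix (including five-digit
internal serials), and records every injection in a manifest.  Scanning a
generated corpus and comparing against the manifest is the keystone
end-to-end test: recall and precision must both be 1.0.

Everything is reproducible from the seed; no network code exists anywhere
in this package.
"""

from __future__ import annotations

import csv
import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from .autoconvert import simulate
from .excel_dates import date_to_serial
from .gene_dictionary import GeneDictionary, bundled_dictionary
from .months import BUILTIN_TABLES, MonthTable

__all__ = [
    "InjectionRecord",
    "CorpusManifest",
    "ConfigError",
    "DEFAULT_CLASS_MIX",
    "generate_corpus",
    "load_manifest",
]

#: Default injection mix, echoing the observed composition of errors in the
#: wild: month-day dates dominate, five-digit serials are the next biggest
#: class, slash dates and scientific floats are rare.
DEFAULT_CLASS_MIX: dict[str, float] = {
    "d-mmm": 0.55,
    "mmm-d": 0.20,
    "five-digit-serial": 0.15,
    "slash-date": 0.07,
    "scientific": 0.03,
}

_SAFE_FILLER = ("sampleA", "sampleB", "control", "treated", "input")


class ConfigError(ValueError):
    """Inconsistent generator configuration."""


@dataclass(frozen=True)
class InjectionRecord:
    """Ground truth for one injected error."""

    file: str
    sheet: str
    column: int
    row: int
    error_class: str
    original: str
    injected: str


@dataclass
class CorpusManifest:
    """All injections plus the file → publication mapping."""

    records: list[InjectionRecord] = field(default_factory=list)
    publication_of: dict[str, str] = field(default_factory=dict)
    files: list[str] = field(default_factory=list)

    def write(self, path: Union[str, Path]) -> None:
        """One row per injection, plus a bare row per clean file so the
        file → publication mapping round-trips."""
        injected_files = {r.file for r in self.records}
        with open(path, "w", newline="", encoding="utf-8") as handle:
            writer = csv.writer(handle, delimiter="\t")
            writer.writerow(
                ["file", "sheet", "column", "row", "error_class", "original",
                 "injected", "publication"]
            )
            for r in self.records:
                writer.writerow(
                    [r.file, r.sheet, r.column, r.row, r.error_class,
                     r.original, r.injected, self.publication_of[r.file]]
                )
            for file in sorted(self.publication_of):
                if file not in injected_files:
                    writer.writerow(
                        [file, "", "", "", "", "", "", self.publication_of[file]]
                    )

    def key_set(self) -> set[tuple[str, str, int, int, str]]:
        return {
            (r.file, r.sheet, r.column, r.row, r.error_class) for r in self.records
        }


def load_manifest(path: Union[str, Path]) -> CorpusManifest:
    manifest = CorpusManifest()
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        for row in reader:
            manifest.publication_of[row["file"]] = row["publication"]
            if not row["error_class"]:
                continue
            manifest.records.append(
                InjectionRecord(
                    file=row["file"],
                    sheet=row["sheet"],
                    column=int(row["column"]),
                    row=int(row["row"]),
                    error_class=row["error_class"],
                    original=row["original"],
                    injected=row["injected"],
                )
            )
    manifest.files = sorted(manifest.publication_of)
    return manifest


def _vulnerability_pools(
    dictionary: GeneDictionary, tables: Sequence[MonthTable]
) -> dict[str, list[str]]:
    """Symbols usable as injection sources, per error class."""
    day_pool: list[str] = []
    year_pool: list[str] = []
    sci_pool: list[str] = []
    for norm in sorted(dictionary.symbols):
        original = dictionary.original(norm)
        result = simulate(original, tables)
        if result.outcome == "date":
            if result.parsed.day is not None:
                day_pool.append(original)
            else:
                year_pool.append(original)
        elif result.outcome == "scientific":
            sci_pool.append(original)
    return {
        "d-mmm": day_pool,
        "mmm-d": day_pool,
        "slash-date": day_pool,
        "iso-date": day_pool,
        "five-digit-serial": day_pool,
        "mmm-yy": year_pool,
        "scientific": sci_pool,
    }


def _safe_pool(
    dictionary: GeneDictionary, tables: Sequence[MonthTable]
) -> list[str]:
    return [
        dictionary.original(norm)
        for norm in sorted(dictionary.symbols)
        if not simulate(dictionary.original(norm), tables).converted
    ]


def _corrupt(
    symbol: str,
    error_class: str,
    tables: Sequence[MonthTable],
    year: int,
) -> str:
    """Render the corrupted display text for *symbol* under *error_class*."""
    if error_class == "scientific":
        return simulate(symbol, tables).display
    result = simulate(symbol, tables, render="mmm-d" if error_class == "mmm-d" else "d-mmm")
    parsed = result.parsed
    if error_class in ("d-mmm", "mmm-d", "mmm-yy"):
        return result.display
    if error_class == "slash-date":
        return f"{parsed.month}/{parsed.day}/{year}"
    if error_class == "iso-date":
        return f"{year:04d}-{parsed.month:02d}-{parsed.day:02d}"
    if error_class == "five-digit-serial":
        return str(date_to_serial(dt.date(year, parsed.month, parsed.day)))
    raise ConfigError(f"unknown error class: {error_class}")


def generate_corpus(
    out_dir: Union[str, Path],
    n_publications: int = 100,
    files_per_pub: tuple[int, int] = (1, 3),
    gene_column_prob: float = 0.8,
    error_rate: float = 0.05,
    class_mix: Optional[Mapping[str, float]] = None,
    dictionary: Optional[GeneDictionary] = None,
    seed: int = 0,
    *,
    n_rows: int = 25,
    xlsx_fraction: float = 0.5,
    tables: Sequence[MonthTable] = BUILTIN_TABLES,
    inject_year: int = 2019,
    min_intact: int = 5,
) -> CorpusManifest:
    """Write a synthetic corpus under *out_dir* and return its manifest.

    Each publication gets 1 or more supplementary files; each file's middle
    column is a gene list with probability *gene_column_prob*.  Vulnerable
    cells are replaced by their rendered conversion with probability
    *error_rate*, with the error class drawn from *class_mix*.  At least
    *min_intact* intact symbols are kept per gene column so the column
    remains detectable.
    """
    if not 0.0 <= error_rate <= 1.0:
        raise ConfigError(f"error_rate outside [0, 1]: {error_rate}")
    mix = dict(class_mix or DEFAULT_CLASS_MIX)
    if any(w < 0 for w in mix.values()):
        raise ConfigError("negative class weight")
    total_weight = sum(mix.values())
    if total_weight <= 0:
        raise ConfigError("class mix has zero total weight")
    classes = sorted(mix)
    weights = np.array([mix[c] for c in classes], dtype=float) / total_weight

    dictionary = dictionary or bundled_dictionary()
    pools = _vulnerability_pools(dictionary, tables)
    for error_class in classes:
        if mix[error_class] > 0 and not pools.get(error_class):
            raise ConfigError(
                f"class {error_class!r} has weight but the dictionary holds "
                "no symbols vulnerable to it"
            )
    safe = _safe_pool(dictionary, tables)
    if len(safe) < min_intact:
        raise ConfigError("dictionary holds too few safe symbols")

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    manifest = CorpusManifest()

    for pub_index in range(n_publications):
        pub_id = f"PUB{pub_index:04d}"
        pub_dir = out_dir / pub_id
        pub_dir.mkdir(exist_ok=True)
        n_files = int(rng.integers(files_per_pub[0], files_per_pub[1] + 1))
        for file_index in range(n_files):
            use_xlsx = rng.random() < xlsx_fraction
            suffix = "xlsx" if use_xlsx else "tsv"
            file_path = pub_dir / f"supp{file_index + 1}.{suffix}"
            grid, injections = _build_sheet(
                rng, dictionary, pools, safe, classes, weights,
                gene_column_prob, error_rate, n_rows, tables,
                inject_year, min_intact,
            )
            sheet_name = "Sheet1" if use_xlsx else file_path.stem
            if use_xlsx:
                _write_xlsx(file_path, sheet_name, grid)
            else:
                with open(file_path, "w", newline="", encoding="utf-8") as handle:
                    csv.writer(handle, delimiter="\t").writerows(grid)
            manifest.publication_of[str(file_path)] = pub_id
            manifest.files.append(str(file_path))
            for column, row, error_class, original, injected in injections:
                manifest.records.append(
                    InjectionRecord(
                        file=str(file_path),
                        sheet=sheet_name,
                        column=column,
                        row=row,
                        error_class=error_class,
                        original=original,
                        injected=injected,
                    )
                )
    return manifest


def _build_sheet(
    rng: np.random.Generator,
    dictionary: GeneDictionary,
    pools: Mapping[str, list[str]],
    safe: list[str],
    classes: list[str],
    weights: np.ndarray,
    gene_column_prob: float,
    error_rate: float,
    n_rows: int,
    tables: Sequence[MonthTable],
    inject_year: int,
    min_intact: int,
) -> tuple[list[list[str]], list[tuple[int, int, str, str, str]]]:
    has_gene_column = rng.random() < gene_column_prob
    header = ["id", "gene" if has_gene_column else "condition", "score"]
    grid: list[list[str]] = [header]
    injections: list[tuple[int, int, str, str, str]] = []

    gene_rows: list[int] = []
    for row_index in range(1, n_rows + 1):
        identifier = f"ID{row_index:04d}"
        if has_gene_column:
            middle = safe[int(rng.integers(len(safe)))]
            gene_rows.append(row_index)
        else:
            middle = _SAFE_FILLER[int(rng.integers(len(_SAFE_FILLER)))]
        score = f"{rng.normal(0.0, 2.0):.3f}"
        grid.append([identifier, middle, score])

    if has_gene_column and error_rate > 0:
        max_injections = max(0, len(gene_rows) - min_intact)
        corrupt_rows = [r for r in gene_rows if rng.random() < error_rate]
        corrupt_rows = corrupt_rows[:max_injections]
        for row_index in corrupt_rows:
            error_class = classes[int(rng.choice(len(classes), p=weights))]
            pool = pools[error_class]
            original = pool[int(rng.integers(len(pool)))]
            injected = _corrupt(original, error_class, tables, inject_year)
            grid[row_index][1] = injected
            injections.append((1, row_index, error_class, original, injected))
    return grid, injections


def _write_xlsx(path: Path, sheet_name: str, grid: list[list[str]]) -> None:
    from openpyxl import Workbook

    workbook = Workbook()
    sheet = workbook.active
    sheet.title = sheet_name
    for row in grid:
        # explicit strings: openpyxl must not re-type injected values
        sheet.append([str(cell) for cell in row])
    workbook.save(path)
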