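"""Corpus-level aggregation: prevalence by group, error-class composition,
and the impact-factor correlation.

Proportions are computed exactly from integer counts and displayed with
half-up rounding to one decimal, matching how prevalence tables are
conventionally printed.
"""

from __future__ import annotations

import json
import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Optional, Sequence

from scipy import stats

from .excel_dates import DisplayDate
from .scanner import ErrorRecord, PublicationStats

logger = logging.getLogger(__name__)

__all__ = [
    "CorpusSummary",
    "ClassComposition",
    "CorrelationResult",
    "InsufficientDataError",
    "round_half_up",
    "display_proportion",
    "aggregate",
    "error_class_composition",
    "share_of_classes",
    "jif_correlation",
    "summaries_to_tsv",
    "summaries_to_json",
]


def round_half_up(value: float | Decimal, digits: int = 1) -> float:
    """Round with ties away from zero (the convention of printed tables)."""
    quantum = Decimal(1).scaleb(-digits)
    return float(Decimal(str(value)).quantize(quantum, rounding=ROUND_HALF_UP))


def display_proportion(numerator: int, denominator: int, digits: int = 1) -> float:
    """Exact percentage from integer counts, display-rounded half-up."""
    if denominator == 0:
        return 0.0
    exact = Decimal(100 * numerator) / Decimal(denominator)
    return float(exact.quantize(Decimal(1).scaleb(-digits), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CorpusSummary:
    """Prevalence of affected publications within one group."""

    group_key: str
    n_with_gene_lists: int
    n_affected: int
    undefined: bool = False  # no gene-list publications in the group

    def __post_init__(self) -> None:
        if self.n_affected > self.n_with_gene_lists:
            raise ValueError("affected count exceeds gene-list count")

    @property
    def proportion(self) -> float:
        """Unrounded affected percentage (0 when undefined)."""
        if self.n_with_gene_lists == 0:
            return 0.0
        return 100.0 * self.n_affected / self.n_with_gene_lists

    @property
    def display(self) -> float:
        """Half-up one-decimal percentage as printed."""
        return display_proportion(self.n_affected, self.n_with_gene_lists)


def aggregate(
    per_publication: Mapping[str, PublicationStats],
    group_of: Mapping[str, str],
) -> list[CorpusSummary]:
    """One summary row per group of publications.

    Publications missing from *group_of* are counted under ``unknown`` and
    logged.  Denominators count publications with at least one gene-list
    file; affected publications are always a subset of those.
    """
    with_lists: Counter = Counter()
    affected: Counter = Counter()
    for pub_id, stats_ in per_publication.items():
        group = group_of.get(pub_id)
        if group is None:
            logger.warning("publication %s has no group; counted as unknown", pub_id)
            group = "unknown"
        if stats_.has_gene_list:
            with_lists[group] += 1
            if stats_.affected:
                affected[group] += 1
    groups = sorted(set(with_lists) | set(affected) | set(group_of.values()))
    out = []
    for group in groups:
        n_lists = with_lists.get(group, 0)
        out.append(
            CorpusSummary(
                group_key=group,
                n_with_gene_lists=n_lists,
                n_affected=affected.get(group, 0),
                undefined=n_lists == 0,
            )
        )
    return out


@dataclass
class ClassComposition:
    """Error-class composition over affected files.

    A file is counted once per class it exhibits, so class file counts can
    overlap; ``multi_class_files`` reports the overlap size.  For
    five-digit-serial records, ``month_histogram`` tallies decoded months
    per file and ``march_september_share`` is the percentage of serial-error
    files whose decoded dates fall in March or September.
    """

    n_affected_files: int = 0
    file_counts: dict[str, int] = field(default_factory=dict)
    percentages: dict[str, float] = field(default_factory=dict)
    month_histogram: Counter = field(default_factory=Counter)
    march_september_share: Optional[float] = None
    multi_class_files: int = 0


def _decoded_month(record: ErrorRecord) -> Optional[int]:
    if isinstance(record.decoded, DisplayDate):
        return record.decoded.month
    if hasattr(record.decoded, "month"):
        return record.decoded.month
    return None


def error_class_composition(records: Iterable[ErrorRecord]) -> ClassComposition:
    """Per-class affected-file counts and percentages over *records*."""
    classes_by_file: dict[str, set[str]] = defaultdict(set)
    serial_months_by_file: dict[str, set[int]] = defaultdict(set)
    for record in records:
        classes_by_file[record.file].add(record.error_class)
        if record.error_class == "five-digit-serial":
            month = _decoded_month(record)
            if month is not None:
                serial_months_by_file[record.file].add(month)

    out = ClassComposition(n_affected_files=len(classes_by_file))
    for classes in classes_by_file.values():
        for error_class in classes:
            out.file_counts[error_class] = out.file_counts.get(error_class, 0) + 1
        if len(classes) > 1:
            out.multi_class_files += 1
    for error_class, count in sorted(out.file_counts.items()):
        out.percentages[error_class] = display_proportion(
            count, out.n_affected_files
        )

    n_serial_files = len(serial_months_by_file)
    if n_serial_files:
        for months in serial_months_by_file.values():
            for month in months:
                out.month_histogram[month] += 1
        in_march_september = sum(
            1 for months in serial_months_by_file.values() if months & {3, 9}
        )
        out.march_september_share = display_proportion(
            in_march_september, n_serial_files
        )
    return out


def share_of_classes(
    records: Iterable[ErrorRecord], classes: Sequence[str]
) -> float:
    """Display-rounded % of affected files exhibiting any class in *classes*."""
    by_file: dict[str, set[str]] = defaultdict(set)
    for record in records:
        by_file[record.file].add(record.error_class)
    if not by_file:
        return 0.0
    hits = sum(1 for seen in by_file.values() if seen & set(classes))
    return display_proportion(hits, len(by_file))


class InsufficientDataError(ValueError):
    """Fewer than three journals pass the correlation filter."""


@dataclass(frozen=True)
class CorrelationResult:
    pearson_r: float
    pearson_p: float
    spearman_rho: float
    spearman_p: float
    n: int


def jif_correlation(
    summaries: Sequence[CorpusSummary],
    jif: Mapping[str, float],
    min_articles: int = 50,
) -> CorrelationResult:
    """Two-sided Pearson and Spearman tests of JIF vs affected proportion.

    Only journals with at least *min_articles* gene-list publications and a
    supplied impact factor enter; fewer than three such pairs raises
    :class:`InsufficientDataError`.
    """
    pairs = [
        (jif[s.group_key], s.proportion)
        for s in summaries
        if s.n_with_gene_lists >= min_articles and s.group_key in jif
    ]
    if len(pairs) < 3:
        raise InsufficientDataError(
            f"need >= 3 journals with JIF and >= {min_articles} articles; "
            f"got {len(pairs)}"
        )
    x = [p[0] for p in pairs]
    y = [p[1] for p in pairs]
    pearson = stats.pearsonr(x, y)
    spearman = stats.spearmanr(x, y)
    return CorrelationResult(
        pearson_r=float(pearson.statistic),
        pearson_p=float(pearson.pvalue),
        spearman_rho=float(spearman.statistic),
        spearman_p=float(spearman.pvalue),
        n=len(pairs),
    )


def summaries_to_tsv(summaries: Sequence[CorpusSummary]) -> str:
    lines = ["group\tn_with_gene_lists\tn_affected\tproportion_pct"]
    for s in summaries:
        lines.append(
            f"{s.group_key}\t{s.n_with_gene_lists}\t{s.n_affected}\t{s.display:.1f}"
        )
    return "\n".join(lines) + "\n"


def summaries_to_json(summaries: Sequence[CorpusSummary]) -> str:
    """Monthly-report style JSON for automated publishing."""
    payload = [
        {
            "group": s.group_key,
            "n_with_gene_lists": s.n_with_gene_lists,
            "n_affected": s.n_affected,
            "proportion_pct": s.display,
            "undefined": s.undefined,
        }
        for s in summaries
    ]
    return json.dumps(payload, indent=2, sort_keys=True)
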