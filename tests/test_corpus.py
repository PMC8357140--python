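import datetime as dt
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from genescreen.corpus import (
    ClassComposition,
    CorpusSummary,
    InsufficientDataError,
    aggregate,
    display_proportion,
    error_class_composition,
    jif_correlation,
    round_half_up,
    share_of_classes,
    summaries_to_json,
    summaries_to_tsv,
)
from genescreen.excel_dates import parse_display_date, serial_to_date
from genescreen.scanner import ErrorRecord, PublicationStats


def stats_for(affected: bool) -> PublicationStats:
    return PublicationStats(
        files_screened=1,
        files_with_gene_lists=1,
        files_affected=int(affected),
    )


def build_group(prefix, group, n_with, n_affected, per_publication, group_of):
    for i in range(n_with):
        pub = f"{prefix}{i}"
        per_publication[pub] = stats_for(i < n_affected)
        group_of[pub] = group


class TestDisplayRounding:
    @pytest.mark.parametrize(
        "num,den,expected",
        [(282, 936, 30.1), (609, 1577, 38.6), (0, 10, 0.0),
         (345, 920, 37.5), (3436, 11117, 30.9)],
    )
    def test_proportions(self, num, den, expected):
        assert display_proportion(num, den) == expected

    def test_half_up(self):
        assert round_half_up(0.25, 1) == 0.3
        assert round_half_up(0.35, 1) == 0.4


class TestAggregate:
    def test_printed_contingency_rows(self):
        per_publication, group_of = {}, {}
        build_group("y", "2014", 936, 282, per_publication, group_of)
        build_group("m", "mouse", 1577, 609, per_publication, group_of)
        build_group("r", "rice", 10, 0, per_publication, group_of)
        summaries = {s.group_key: s for s in aggregate(per_publication, group_of)}
        assert summaries["2014"].display == 30.1
        assert summaries["mouse"].display == 38.6
        assert summaries["rice"].display == 0.0

    def test_conservation_across_groups(self):
        per_publication, group_of = {}, {}
        build_group("a", "g1", 20, 5, per_publication, group_of)
        build_group("b", "g2", 30, 10, per_publication, group_of)
        summaries = aggregate(per_publication, group_of)
        assert sum(s.n_with_gene_lists for s in summaries) == 50
        assert sum(s.n_affected for s in summaries) == 15

    def test_missing_group_goes_to_unknown(self, caplog):
        per_publication = {"p1": stats_for(True)}
        with caplog.at_level("WARNING"):
            summaries = aggregate(per_publication, {})
        assert summaries[0].group_key == "unknown"

    def test_empty_group_flagged(self):
        summaries = aggregate({}, {"ghost": "empty-group"})
        (summary,) = summaries
        assert summary.undefined
        assert summary.proportion == 0.0

    def test_affected_cannot_exceed_gene_lists(self):
        with pytest.raises(ValueError):
            CorpusSummary("g", n_with_gene_lists=1, n_affected=2)

    def test_serialization(self):
        summaries = [CorpusSummary("2014", 936, 282)]
        assert "30.1" in summaries_to_tsv(summaries)
        assert '"proportion_pct": 30.1' in summaries_to_json(summaries)


def date_record(file, raw, error_class=None):
    parsed = parse_display_date(raw)
    if parsed is not None:
        cls = {"d-mmm": "d-mmm", "mmm-d": "mmm-d", "mmm-yy": "mmm-yy",
               "slash": "slash-date", "iso": "iso-date"}[parsed.source_format]
        return ErrorRecord(file, "S", 0, 0, raw, cls, parsed)
    serial = int(raw)
    return ErrorRecord(file, "S", 0, 0, raw, "five-digit-serial",
                       serial_to_date(serial))


class TestComposition:
    def test_counts_and_shares(self):
        records = [
            date_record("f1", "1-Mar"),
            date_record("f1", "7-Sep"),   # same file, same class family
            date_record("f2", "Mar-3"),
            date_record("f3", "43709"),
        ]
        composition = error_class_composition(records)
        assert composition.n_affected_files == 3
        # a file counts once per class it exhibits
        assert composition.file_counts == {
            "d-mmm": 1, "mmm-d": 1, "five-digit-serial": 1,
        }
        assert share_of_classes(records, ["d-mmm", "mmm-d"]) == display_proportion(2, 3)

    def test_month_histogram_and_march_september_share(self):
        records = [
            date_record("f1", "43709"),  # 2019-09-01
            date_record("f2", str(43525 + 10)),  # March 2019
            date_record("f3", str(43101)),  # 2018-01-01
        ]
        composition = error_class_composition(records)
        assert composition.month_histogram[9] == 1
        assert composition.march_september_share == display_proportion(2, 3)

    def test_overlap_reported(self):
        records = [date_record("f1", "1-Mar"), date_record("f1", "43709")]
        composition = error_class_composition(records)
        assert composition.multi_class_files == 1
        # percentages over overlapping classes may sum past 100
        assert sum(composition.file_counts.values()) == 2

    def test_empty(self):
        composition = error_class_composition([])
        assert composition.n_affected_files == 0
        assert composition.march_september_share is None


def pearson_oracle(x, y):
    """Textbook covariance formula plus the exact t-distribution p-value."""
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    r = sxy / math.sqrt(sxx * syy)
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * math.sqrt((n - 2) / (1 - r * r))
    return r, 2 * sps.t.sf(abs(t), n - 2)


def rank_oracle(values):
    """Average ranks, written out by hand (no library rank call)."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


class TestJifCorrelation:
    def _summaries(self, pairs):
        out, jif = [], {}
        for i, (x, y) in enumerate(pairs):
            journal = f"J{i}"
            n_with = 100
            out.append(CorpusSummary(journal, n_with, round(n_with * y / 100)))
            jif[journal] = x
        return out, jif

    def test_perfect_positive(self):
        summaries, jif = self._summaries([(1, 10), (2, 20), (3, 30)])
        result = jif_correlation(summaries, jif)
        assert result.pearson_r == pytest.approx(1.0)
        assert result.spearman_rho == pytest.approx(1.0)

    def test_perfect_negative(self):
        summaries, jif = self._summaries([(1, 30), (2, 20), (3, 10)])
        result = jif_correlation(summaries, jif)
        assert result.pearson_r == pytest.approx(-1.0)

    def test_min_articles_filter(self):
        summaries = [CorpusSummary("J1", 100, 30), CorpusSummary("J2", 100, 20),
                     CorpusSummary("J3", 100, 10), CorpusSummary("small", 5, 1)]
        jif = {"J1": 1.0, "J2": 2.0, "J3": 3.0, "small": 50.0}
        result = jif_correlation(summaries, jif, min_articles=50)
        assert result.n == 3

    def test_insufficient_data(self):
        summaries, jif = self._summaries([(1, 10), (2, 20)])
        with pytest.raises(InsufficientDataError):
            jif_correlation(summaries, jif)

    def test_matches_formula_oracle_on_random_tables(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(5, 40))
            x = rng.normal(5, 2, size=n).tolist()
            y = (rng.uniform(0, 50, size=n)).tolist()
            summaries = [CorpusSummary(f"J{i}", 1000, round(10 * y[i]))
                         for i in range(n)]
            jif = {f"J{i}": x[i] for i in range(n)}
            result = jif_correlation(summaries, jif, min_articles=1)
            r, p = pearson_oracle(x, [s.proportion for s in summaries])
            assert result.pearson_r == pytest.approx(r, abs=1e-6)
            assert result.pearson_p == pytest.approx(p, abs=1e-6)
            rho, rho_p = pearson_oracle(rank_oracle(x),
                                        rank_oracle([s.proportion for s in summaries]))
            assert result.spearman_rho == pytest.approx(rho, abs=1e-6)
            assert result.spearman_p == pytest.approx(rho_p, abs=1e-6)
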