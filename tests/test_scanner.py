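import datetime as dt

import pytest

from genescreen.spreadsheet_io import Table, read_tables
from genescreen.scanner import (
    DEFAULT_CONFIG,
    ErrorRecord,
    GroupingError,
    ScanConfig,
    ScanReport,
    classify_cell,
    combine_reports,
    detect_gene_columns,
    rollup_publications,
    scan_file,
    scan_table,
)


def column_table(*columns):
    rows = list(zip(*columns))
    return Table("mem", "S", [list(r) for r in rows])


class TestDetectGeneColumns:
    def test_ten_symbols_qualify(self, small_dict):
        table = column_table(["TP53", "BRCA1", "EGFR", "KRAS", "MYC",
                              "GAPDH", "ACTB", "SEPT1", "MARCH1", "DEC1"])
        assert detect_gene_columns(table, small_dict) == [0]

    def test_four_symbols_do_not_qualify(self, small_dict):
        table = column_table(
            ["TP53", "BRCA1", "EGFR", "KRAS", "1", "2", "3", "4", "5", "6"]
        )
        assert detect_gene_columns(table, small_dict) == []

    def test_five_symbols_plus_date_qualify(self, small_dict):
        table = column_table(["TP53", "BRCA1", "EGFR", "KRAS", "MYC", "7-Sep"])
        assert detect_gene_columns(table, small_dict) == [0]

    def test_threshold_counts_intact_only(self, small_dict):
        # four intact + three converted: below threshold by design
        table = column_table(["TP53", "BRCA1", "EGFR", "KRAS",
                              "7-Sep", "1-Mar", "4-Oct"])
        assert detect_gene_columns(table, small_dict) == []

    def test_custom_threshold(self, small_dict):
        table = column_table(["TP53", "BRCA1", "EGFR"])
        assert detect_gene_columns(table, small_dict, min_hits=3) == [0]


class TestClassifyCell:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("3-Mar", "d-mmm"),
            ("Mar-3", "mmm-d"),
            ("Jan-41", "mmm-yy"),
            ("3/1/2016", "slash-date"),
            ("2016-03-01", "iso-date"),
            ("9.33E+22", "scientific"),
            ("43709", "five-digit-serial"),
        ],
    )
    def test_classes(self, raw, expected):
        error_class, _ = classify_cell(raw)
        assert error_class == expected

    def test_five_digit_decodes(self):
        _, decoded = classify_cell("43709")
        assert decoded == dt.date(2019, 9, 1)

    @pytest.mark.parametrize("raw", ["TP53", "", "gene", "04321", "9999",
                                     "100000", "4321", "0.05"])
    def test_non_errors(self, raw):
        assert classify_cell(raw) is None

    def test_intact_symbols_never_flagged(self, fixture_dict):
        # includes scientific-shaped identifiers like 2310009E13
        for norm in fixture_dict.symbols:
            original = fixture_dict.original(norm)
            assert classify_cell(original, dictionary=fixture_dict) is None

    def test_serial_tag_enriches_decoded_date(self):
        _, decoded = classify_cell("1-Sep", serial_tag=43709)
        assert decoded == dt.date(2019, 9, 1)

    def test_serial_tag_flags_unrecognized_display(self):
        hit = classify_cell("01 September 2019", serial_tag=43709)
        assert hit is not None
        assert hit[0] == "five-digit-serial"

    def test_narrow_window_config(self):
        config = ScanConfig(serial_window=(43000, 44000))
        assert classify_cell("43709", config=config) is not None
        assert classify_cell("20000", config=config) is None


def write_fixture_file(gene_column_tsv, injected):
    symbols = ["TP53", "BRCA1", "EGFR", "KRAS", "MYC", "GAPDH", "ACTB",
               "SEPT1", "MARCH1", "DEC1"]
    rows = [["id", "gene", "score"]]
    for i, symbol in enumerate(symbols):
        rows.append([f"ID{i}", symbol, "0.5"])
    for offset, value in enumerate(injected):
        rows.append([f"IDX{offset}", value, "0.5"])
    return gene_column_tsv(rows)


class TestScanFile:
    def test_injected_dates_flagged(self, gene_column_tsv, small_dict):
        injected = ["7-Sep", "1-Mar", "Jan-41", "3/1/2016", "9.33E+22",
                    "43709", "Sep-02"]
        path = write_fixture_file(gene_column_tsv, injected)
        report = scan_file(path, small_dict)
        assert report.files_screened == 1
        assert report.files_with_gene_lists == 1
        assert report.files_affected == 1
        assert len(report.records) == 7
        assert {r.raw for r in report.records} == set(injected)

    def test_dates_outside_gene_columns_ignored(self, gene_column_tsv,
                                                small_dict):
        rows = [["date", "gene"]]
        for i, symbol in enumerate(["TP53", "BRCA1", "EGFR", "KRAS", "MYC"]):
            rows.append(["7-Sep", symbol])
        path = gene_column_tsv(rows)
        report = scan_file(path, small_dict)
        assert report.records == []
        assert report.files_affected == 0

    def test_five_digit_serial_record(self, gene_column_tsv, small_dict):
        path = write_fixture_file(gene_column_tsv, ["43709"])
        report = scan_file(path, small_dict)
        (record,) = report.records
        assert record.error_class == "five-digit-serial"
        assert record.decoded == dt.date(2019, 9, 1)

    def test_unknown_file_logged_not_raised(self, tmp_path, small_dict):
        path = tmp_path / "blob.xlsx"
        path.write_bytes(bytes([0, 1, 2]) * 20)
        report = scan_file(path, small_dict)
        assert report.files_screened == 1
        assert report.skipped == [str(path)]
        assert report.records == []

    def test_xlsx_date_cell_flagged_via_serial(self, make_xlsx, small_dict):
        grid = [["gene"]] + [[s] for s in
                             ["TP53", "BRCA1", "EGFR", "KRAS", "MYC"]]
        grid.append([(dt.datetime(2019, 9, 1), "d-mmm")])
        path = make_xlsx({"S1": grid})
        report = scan_file(path, small_dict)
        (record,) = report.records
        assert record.error_class == "d-mmm"
        assert record.decoded == dt.date(2019, 9, 1)

    def test_context_cells_recorded(self, gene_column_tsv, small_dict):
        path = write_fixture_file(gene_column_tsv, ["7-Sep"])
        report = scan_file(path, small_dict)
        (record,) = report.records
        assert record.context  # neighbours for human review
        assert len(record.context) <= DEFAULT_CONFIG.context_cells

    def test_report_invariants(self, gene_column_tsv, small_dict):
        path = write_fixture_file(gene_column_tsv, ["7-Sep", "43709"])
        report = scan_file(path, small_dict)
        report.validate()
        assert sum(report.per_class_counts.values()) == len(report.records)


class TestTransposedFlag:
    def test_horizontal_list_needs_flag(self, gene_column_tsv, small_dict):
        row = ["TP53", "BRCA1", "EGFR", "KRAS", "MYC", "7-Sep"]
        path = gene_column_tsv([row, ["1"] * len(row)])
        assert scan_file(path, small_dict).records == []
        config = ScanConfig(scan_transposed=True)
        report = scan_file(path, small_dict, config)
        assert len(report.records) == 1
        record = report.records[0]
        assert (record.row, record.column) == (0, 5)


class TestRollup:
    def _report(self, path, affected):
        report = ScanReport(files_screened=1, files_with_gene_lists=1,
                            files_affected=int(affected), path=path)
        if affected:
            report.records = [ErrorRecord(path, "S", 0, 0, "7-Sep", "d-mmm")]
        return report

    def test_one_publication_two_affected(self):
        reports = [self._report("a", True), self._report("b", True),
                   self._report("c", False)]
        rollup = rollup_publications(reports, {"a": "P1", "b": "P1", "c": "P1"})
        assert rollup.publications_affected == 1
        assert rollup.affected_files == 2

    def test_clean_publications(self):
        reports = [self._report("a", False), self._report("b", False)]
        rollup = rollup_publications(reports, {"a": "P1", "b": "P2"})
        assert rollup.publications_affected == 0
        assert rollup.publications_with_gene_lists == 2

    def test_missing_mapping_raises(self):
        with pytest.raises(GroupingError):
            rollup_publications([self._report("a", True)], {})

    def test_order_invariance(self, gene_column_tsv, small_dict):
        p1 = write_fixture_file(gene_column_tsv, ["7-Sep"])
        reports = [scan_file(p1, small_dict)]
        forward = combine_reports(reports)
        backward = combine_reports(list(reversed(reports)))
        assert forward.files_affected == backward.files_affected
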