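import datetime as dt
from pathlib import Path

import pytest
from openpyxl import Workbook

from genescreen.gene_dictionary import GeneDictionary, bundled_dictionary


@pytest.fixture(scope="session")
def fixture_dict() -> GeneDictionary:
    return bundled_dictionary()


@pytest.fixture
def small_dict() -> GeneDictionary:
    return GeneDictionary.from_symbols(
        ["SEPT1", "SEPT7", "MARCH1", "MARCH3", "DEC1", "OCT4", "TP53", "NCF1",
         "BRCA1", "EGFR", "KRAS", "MYC", "GAPDH", "ACTB"],
        renames={"SEPT1": "SEPTIN1", "MARCH1": "MARCHF1"},
    )


@pytest.fixture
def make_xlsx(tmp_path):
    """Factory writing an xlsx from {sheet_name: grid}; values pass through
    untyped unless given as (value, number_format) pairs."""

    def _make(sheets: dict, name: str = "book.xlsx") -> Path:
        path = tmp_path / name
        workbook = Workbook()
        workbook.remove(workbook.active)
        for sheet_name, grid in sheets.items():
            sheet = workbook.create_sheet(sheet_name)
            for r, row in enumerate(grid, start=1):
                for c, value in enumerate(row, start=1):
                    if isinstance(value, tuple):
                        value, number_format = value
                        cell = sheet.cell(row=r, column=c, value=value)
                        cell.number_format = number_format
                    else:
                        sheet.cell(row=r, column=c, value=value)
        workbook.save(path)
        return path

    return _make


@pytest.fixture
def gene_column_tsv(tmp_path):
    """TSV whose middle column is a gene list with known injected errors."""

    def _make(cells, name="table.tsv") -> Path:
        path = tmp_path / name
        lines = ["\t".join(row) for row in cells]
        path.write_text("\n".join(lines) + "\n")
        return path

    return _make


SAMPLE_GTF = """\
#!genome-build fixture
chr1\thavana\tgene\t100\t900\t.\t+\t.\tgene_id "G1"; gene_name "SEPT4";
chr1\thavana\ttranscript\t100\t900\t.\t+\t.\tgene_id "G1"; gene_name "SEPT4";
chr2\thavana\tgene\t200\t800\t.\t-\t.\tgene_id "G2"; gene_name "Actb";
chr2\thavana\tgene\t250\t850\t.\t-\t.\tgene_id "G3"; gene_name "Actb";
"""


@pytest.fixture
def gtf_file(tmp_path) -> Path:
    path = tmp_path / "anno.gtf"
    path.write_text(SAMPLE_GTF)
    return path
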