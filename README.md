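# genescreen

Detect, classify and repair spreadsheet autoconversion damage ("gene name
errors") in supplementary gene lists, simulate the autoconversion behaviour
of spreadsheet software to screen any gene-name catalogue for vulnerable
symbols, and aggregate findings into corpus-level prevalence reports.

Spreadsheets silently convert gene symbols like `SEPT7` into dates
(`7-Sep`), RIKEN-style identifiers like `2310009E13` into floats
(`2.310009E+19`), and — after a cell-format change — dates into five-digit
internal serials (`43709` = 1 Sep 2019). This package finds all of these in
published supplementary files, suggests reversals, and reports prevalence.

## Layout

| module            | role |
|-------------------|------|
| `excel_dates`     | 1900-system serial-date arithmetic, display-date parsing, five-digit candidate windows |
| `gene_dictionary` | symbol sets, normalization, GTF `gene_name` extraction, bundled fixture dictionary + renames |
| `months`          | locale month-token tables (English, Italian/Spanish/Portuguese, Dutch, Finnish; TSV-loadable) |
| `autoconvert`     | deterministic autoconversion simulator, catalogue screening, `jun-1` name-arithmetic evaluation |
| `spreadsheet_io`  | content-sniffed reading of XLSX/CSV/TSV into string tables with date-serial tags |
| `scanner`         | gene-column detection (≥5 intact symbols), cell classification, per-file/per-publication rollups |
| `repair`          | reverse-mapping of flagged cells to candidate symbols (+ modernized names) |
| `corpus`          | grouped prevalence summaries, error-class composition, JIF correlation |
| `synth`           | seeded synthetic corpora with ground-truth injection manifests |
| `harvest`         | offline `.xls`/`.xlsx` link extraction from saved article HTML |

## CLI

```sh
# screen files (exit 0 clean, 3 when errors found)
genescreen scan supp_table.xlsx --tsv flagged.tsv --json summary.json

# what would a spreadsheet do to these strings?
genescreen simulate SEPT7 MARCH3 TP53 2310009E13
genescreen simulate TAMM41 --locale fi

# screen a gene catalogue (GTF or plain list) for vulnerable names
genescreen screen-names --gtf annotation.gtf

# suggest reversals (side file only; inputs are never modified)
genescreen repair supp_table.xlsx --tsv fixes.tsv

# synthesize a ground-truth corpus, then report prevalence by group
genescreen synth corpus/ --publications 50 --error-rate 0.1 --seed 1
genescreen report corpus/ --pubmap pubmap.tsv --jif jif.tsv

# pull supplementary spreadsheet links out of saved article pages
genescreen links article.html
```

`pubmap.tsv` maps `file → publication id → group label`; `jif.tsv` maps
`journal → impact factor` (impact factors are user-supplied).

## Notes

- OLE `.xls` workbooks are recognized by magic bytes but need `xlrd` to be
  read; without it they are logged skips. Misnamed text files with `.xls`
  suffixes (a common case) are sniffed and read as delimited text.
- No module performs network access; harvesting operates on pre-saved HTML.
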