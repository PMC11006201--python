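# data/

Place a local copy of the original deposited respondent table here to
enable the deposited-data acceptance checks:

* `s1_dataset.xlsx` (re-save the deposited XLS as XLSX), or
* `s1_dataset.csv`

Expected columns: the canonical item names `phq1..phq9`, `gad1..gad7`,
`sss1..sss8`, `pss1..pss10`, `osss1..osss3`, an `age` column, and the
covariate columns; `nrsem.io.load_survey` accepts a column map for files
with different headers.

The table is third-party research data and is not redistributed with this
repository.
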