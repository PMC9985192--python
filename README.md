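# phenocheck

Pre-submission validation, repair, labelling and reporting for
dbGaP-formatted subject phenotype files.

## The problem

The NIH Database of Genotypes and Phenotypes (dbGaP) archives study data as
pairs of tab-delimited text files: a **subject phenotype data set** (one row
per participant, first column a subject identifier, one column per
phenotype variable) and its **data dictionary** (one row per variable with
name `VARNAME`, description `VARDESC`, units `UNITS`, and a
`value = meaning` map `VALUES`, e.g. `0=no`, `1=yes`, `-9999=missing
value`). Curating large studies into this contract by hand is error-prone:
variable lists drift out of sync between the two files, descriptions get
copy-pasted, category codes go undocumented, and user-defined missing-value
codes such as `-9999` and `-4444` are used inconsistently or leak into
summary statistics. phenocheck catches these problems before submission.

On top of the dbGaP-required fields, phenocheck requires `TYPE`, `MIN` and
`MAX` in the dictionary so it can verify variable types and logical bounds;
a repair helper adds them when absent.

## What it does

* **Checks** — a twelve-check panel over the file pair, run in a fixed
  order: required fields (`field_check`, `pkg_field_check`), dimension and
  name concordance (`dimension_check`, `name_check`), subject-ID integrity
  (`id_check`), duplicate/empty rows (`row_check`), missingness encoding
  (`na_check`), duplicate/empty descriptions (`description_check`), type
  conformance (`type_check`), value-map completeness (`values_check`,
  `missing_value_check`) and logical bounds (`minmax_check`, inclusive:
  observed values must satisfy MIN ≤ x ≤ MAX after excluding missing
  codes). Checks whose inputs are guarded by another check are reported
  `not_run` naming the prerequisite.
* **Repairs** — `add_missing_fields` (infers `TYPE` from the data, adds
  empty `MIN`/`MAX` columns) and `reorder_dictionary` (aligns dictionary
  row order with the data set). Repairs are pure; inputs are never mutated.
* **Labelling** — `label_data` merges dictionary metadata onto the data set
  with SPSS-style user-missing semantics: cells equal to a declared missing
  code are flagged, not destroyed.
* **Reports** — `create_report` (per-variable descriptives with histograms
  and labelled frequency charts) and `create_awareness_report`
  (missing-code and value-map usage tables), rendered to markdown or
  standalone HTML. Reports are diagnostic and never fail on dirty data.
* **Fixtures** — a seedable generator of clean file pairs plus a
  seventeen-kind error-injection taxonomy, each kind detected by exactly
  one check.

## Worked example

```python
import phenocheck as pc

ds, dd = pc.generate_clean(pc.FixtureSpec(n_subjects=100, seed=42))
report = pc.check_report(ds, dd)
print(report.format_table())
```

prints

```
CHECK                STATUS  MESSAGE
------------------------------------
field_check          PASS    all dbGaP-required dictionary fields present
pkg_field_check      PASS    all package-required dictionary fields present
dimension_check      PASS    12 variables in both files
name_check           PASS    variable names and order agree
id_check             PASS    subject IDs complete and unique
row_check            PASS    no duplicated or empty participant rows
na_check             PASS    missingness encoding consistent
description_check    PASS    variable names and descriptions unique and non-empty
type_check           PASS    observed values compatible with declared types
values_check         PASS    value=meaning maps well-formed and complete
missing_value_check  PASS    all observed missing codes are declared in the value maps
minmax_check         PASS    all observed values within logical MIN/MAX bounds
overall: PASS (0 failed, 0 not run)
```

Now plant one out-of-range value and re-run:

```python
ds2, dd2, manifest = pc.inject_error(ds, dd, "value_above_max", seed=7)
report2 = pc.check_report(ds2, dd2)
print(report2.failed)             # ['minmax_check']
f = report2.result("minmax_check").details[0]
print(f.variable, f.row, f.value)  # VISIT_YEAR 63 2021
```

Exactly one check fails, and its finding names the variable, the 1-based
data row and the offending value — `2021` exceeds the declared `MAX` of
2020 for the visit-year variable.

The same workflow from the shell:

```sh
phenocheck fixture --out-dir demo --seed 42
phenocheck check demo/dataset.txt demo/dictionary.txt --json results.json
phenocheck report demo/dataset.txt demo/dictionary.txt --format html --out report.html
phenocheck fix add-missing-fields demo/dataset.txt demo/dictionary.txt
```

`check` exits 0 when every check passes, 1 on any failure, 2 on a
parse/configuration error.

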