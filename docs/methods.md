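# Methods

This note documents the data model, the semantics of each check, the
synthetic-fixture generator, and the design choices made where the file
contract leaves room.

## The two-file contract

A submission is a pair of tab-delimited UTF-8 text files. The data set has
one header row, one row per participant, the subject identifier in the
first column, and one phenotype variable per remaining column. The data
dictionary has one row per variable and the fields `VARNAME`, `VARDESC`,
`UNITS`, `TYPE`, `MIN`, `MAX` and `VALUES`; the `VALUES` column and every
column to its right hold one `code=meaning` entry per cell (`0=no`,
`-9999=missing value`). The first four fields are required by the
repository; `TYPE`, `MIN` and `MAX` are required by this package because
the type and range checks cannot run without them.

Parsing decisions:

* Field names match case-insensitively with surrounding whitespace
  stripped; canonical upper-case names are written. Hand-edited
  dictionaries routinely vary capitalisation.
* The headers of spill columns right of `VALUES` are ignored on read (real
  files leave them blank or improvise names); empty header cells are
  written. The duplicate-header error therefore applies only to columns at
  or left of `VALUES`.
* `code=meaning` entries split on the **first** `=`: meanings may contain
  `=`, codes never do. Codes keep their sign and leading zeros verbatim.
* Cells are typed by the narrowest parse — integer, then decimal (with
  optional sign and scientific notation), then text; the empty cell is the
  native-missing marker. Tokens like `nan`, `inf` or underscore-grouped
  digits stay text: no curator writes numbers that way. The raw text of
  every cell is preserved, so write∘read is the identity byte-for-byte.
* LF and CRLF are accepted on read, LF written; UTF-8 BOM tolerated on
  read, never written. There is no quoting dialect — a tab inside a cell
  surfaces as a ragged row and is a parse error.
* `read_dictionary` is strict by default (a malformed value entry is a
  parse error naming the row); the lenient mode keeps the raw cell so the
  check panel can report it instead. The CLI reads leniently: a malformed
  entry in a file is a finding of `values_check`, not a crash.

## Missing-value codes

Studies encode missingness with sentinel values. The effective code set
for a variable is the union of the global set (default `{-9999, -4444}`),
per-variable additions from configuration, and codes harvested from the
variable's own value map wherever the meaning matches a case-insensitive
pattern (default: contains "missing", so `-7777=Missing: refused`
contributes `-7777`). Code membership uses normalised numeric comparison —
`-9999`, `-9999.0` and `-9.999e3` are the same code — falling back to exact
string comparison for non-numeric tokens. Cells equal to an effective code
are excluded from type checking, range checking and all report statistics.

## The check panel

Canonical order: `field_check`, `pkg_field_check`, `dimension_check`,
`name_check`, `id_check`, `row_check`, `na_check`, `description_check`,
`type_check`, `values_check`, `missing_value_check`, `minmax_check`.
Every check returns `pass`, `fail` or `not_run`; a check passes exactly
when its `details` list is empty, and purely informational findings live in
a separate `info` list so they never change a verdict.

Prerequisites (a check whose prerequisite did not pass is `not_run` naming
it): `type_check` and `minmax_check` need `pkg_field_check`;
`values_check` and `missing_value_check` need `field_check`; `name_check`
needs `dimension_check`. The last dependency is a deliberate design
choice: a variable-count mismatch necessarily breaks the name-set
comparison too, and reporting both as failures would double-count one
underlying error. With the dependency, each curation mistake maps to
exactly one failing check — the property the error-injection matrix
verifies.

Semantics worth spelling out:

* **Subject-ID dialect.** The dictionary may or may not contain a row for
  the ID column; both occur in practice. Dimension and name comparisons
  include the ID column exactly when the dictionary defines it.
* **row_check** compares rows over their non-ID cells. A participant
  entered twice under a fresh identifier is the realistic duplication
  error; byte-identical rows are still caught, while ID uniqueness itself
  belongs to `id_check`.
* **na_check** reports native-missing (empty-cell) counts per variable and
  flags variables mixing empty cells with missing codes — two encodings of
  the same fact. Rows with no phenotype data at all are excluded first:
  those are a row-level defect owned by `row_check`, and counting them here
  would smear one bad row across every variable. Mixed-encoding findings
  are informational by default (`na_severity: fail` escalates them),
  because the right encoding is a study-level convention, not an error the
  tool can adjudicate.
* **type_check** uses an open TYPE vocabulary matched case-insensitively:
  integer/int; decimal/num/numeric/number/float/double; encoded
  value/encoded (expects integer-like codes); string/char/text and
  date/time labels (accept anything). Unrecognised or empty labels are
  informational findings, not failures. Only the first offending value per
  variable is reported — one bad column should read as one finding.
* **minmax_check** treats bounds as inclusive ("not more extreme than"
  means ≤ and ≥). Non-numeric text cells are skipped there (they are
  `type_check`'s finding); a non-empty bound that does not parse as a
  number is an "unparseable bound" failure; variables with both bounds
  empty are skipped.
* **description_check** compares names and descriptions case-insensitively
  with whitespace collapsed, since near-duplicates are the realistic
  copy-paste error.

## Repairs and labelling

`add_missing_fields` infers `TYPE` per variable from the data (integer →
decimal → string ladder over non-missing cells) and adds `MIN`/`MAX` as
empty columns only: logical bounds are the investigators' knowledge, and
populating them from observed extremes would make the range check
tautological. Inference never emits "encoded value" — category codes are
indistinguishable from plain integers without intent, so encoded types
must be refined by hand. An alignment error is raised only for variables
that actually need inference; a complete dictionary is returned unchanged.
`reorder_dictionary` permutes dictionary rows into data-set column order
and refuses with the symmetric difference when the name sets differ.

`label_data` attaches description, units, value labels (in dictionary
order) and effective missing codes to each variable, and flags cells equal
to a missing code as user-missing without altering them — stripping the
metadata reproduces the input exactly. The pandas view masks user-missing
cells to `NA`; the raw codes remain recoverable from the underlying data
set.

## Reports

`create_report` emits one section per dictionary variable: the counting
table (valid + native-missing + per-code counts always sum to the number
of participants), min/mean/median/max for numeric variables, labelled
frequency tables for encoded and string variables, and a figure. Numeric
histograms use Sturges' rule (k = ⌈log₂ n⌉ + 1) with integer-aligned bin
edges for integer-valued data, and draw `MIN`/`MAX` as dashed reference
lines; categorical variables get a horizontal bar chart with value labels.
Variables with more than 50 distinct strings render a top-20-plus-other
table to bound report size. String variables with no declared type but
fully numeric values are summarised numerically.

Reports are diagnostic, so they must work on exactly the dirty inputs the
checks complain about: by default a name mismatch between the files
produces an "Alignment notes" section and summaries for the intersection
(`strict=True` opts into a hard error instead). `create_awareness_report`
tabulates missing-code usage with map status (table A), encoded values
absent from their maps (table B) and mixed missingness encodings (table
C), with no pass/fail verdicts.

Rendering is deterministic: given the same inputs and a pinned timestamp,
markdown, HTML and every embedded PNG are byte-identical. HTML embeds
figures base64-inline and opens standalone; markdown links PNGs from a
sibling `<stem>_files/` directory.

## Synthetic fixtures

`generate_clean` is the package's primary test surface. The default plan
emulates a small cardiovascular survey: 100 participants and 12 variables —
integer and decimal measurements with investigator-style bounds (age 18–80
years, height 120–210 cm, blood pressures), encoded categories (sex,
smoking status, diabetes), and free-string site/cohort columns. Variables
with a 2–5% missing rate record missingness with `-9999` and declare
`-9999=missing value` in their map, mirroring the convention the checks
enforce; clean fixtures never use empty cells for missingness. Encoded and
string variables carry empty `MIN`/`MAX` (bounds on category codes are
meaningless). Participant rows are drawn jointly with rejection so no two
rows share identical phenotype data, which is what the clean contract
("passes every check") requires; a plan without enough joint entropy for
the requested number of distinct rows is rejected as inconsistent. All
drawing uses one seeded generator, so a (spec, seed) pair yields
byte-identical files everywhere.

What the generator does **not** emulate: correlations between variables,
longitudinal visit structure, genotype data, realistic free-text noise, or
encoding errors beyond the injected taxonomy. A passing panel on synthetic
data therefore demonstrates the checks' detection semantics, not the
messiness profile of any real study.

`inject_error` applies exactly one minimal, seeded perturbation per kind —
one cell, row, field or dictionary entry — so failure attribution is
unambiguous, and returns a manifest naming the location. The seventeen
kinds cover every check in the panel; the diagonal-detection property
(each kind trips its mapped check and nothing else) is exercised with
`na_severity` escalated to `fail` so the mixed-encoding kind registers as
a failure. Probe values are chosen not to collide with other checks: the
type-violation probe stays inside the declared bounds, the out-of-range
probes are integers that are not missing codes, and the duplicated row
keeps its own subject ID.

## Problem sizes

The test suite and the acceptance script use 100-participant default
fixtures, 25–100 random fixture specs for the clean-guarantee and
round-trip properties, and 1,000 random single-variable fixtures for the
range-check and summary-statistic oracle comparisons; the whole suite runs
in well under a minute on one core. These sizes give every code path
(codes, empties, outliers, degenerate all-missing columns) thousands of
chances to disagree with the brute-force oracles while keeping the checks
instant to iterate on.

## Known limitations

* Only the subject phenotype data set and its dictionary are in scope; the
  other submission file types (sample attributes, subject–sample mapping,
  pedigrees, consent files) are not validated here.
* Excel templates and multi-sheet workbooks are not read; export to
  tab-delimited text first.
* Most findings require manual correction by design — the tool flags
  coding mismatches and typographical errors but does not guess fixes.
* Whether labelling should preserve value-label order from the dictionary
  is unspecified in the contract; this implementation preserves dictionary
  order.
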