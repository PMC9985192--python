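"""The integrity-check panel over a (data set, data dictionary) pair.

Twelve checks run in a canonical order, each returning a structured
:class:`CheckResult`.  Checks that need dictionary fields another check
guards (e.g. range checks need TYPE/MIN/MAX) are reported ``not_run`` naming
the unmet prerequisite rather than failing confusingly.  ``check_report``
orchestrates the panel.

Missing-value semantics: studies record missing data with user-defined
sentinel codes such as -9999 or -4444.  A :class:`MissingCodeSpec` collects
the codes in force — a global set, per-variable additions, and codes
harvested from the value map wherever the meaning text denotes missingness
(default pattern: contains "missing").  Code membership is decided by
normalised numeric comparison, so ``-9999`` and ``-9999.0`` are the same
code.  Cells equal to an effective code are excluded from type and range
checking.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Callable, Sequence

from .io import (
    Cell,
    DataDictionary,
    PhenotypeDataset,
    VariableDefinition,
)

__all__ = [
    "MissingCodeSpec",
    "CheckConfig",
    "Finding",
    "CheckResult",
    "CheckReport",
    "PANEL_ORDER",
    "PREREQUISITES",
    "normalize_code",
    "field_check",
    "pkg_field_check",
    "dimension_check",
    "name_check",
    "id_check",
    "row_check",
    "na_check",
    "description_check",
    "type_check",
    "values_check",
    "missing_value_check",
    "minmax_check",
    "check_report",
]

DEFAULT_MISSING_CODES = frozenset({"-9999", "-4444"})

REQUIRED_FIELDS = ("VARNAME", "VARDESC", "UNITS", "VALUES")
PKG_REQUIRED_FIELDS = ("TYPE", "MIN", "MAX")


def normalize_code(token: str) -> str:
    """Canonical token for code comparison: numeric when possible.

    ``"-9999"`` and ``"-9999.0"`` normalise identically; non-numeric tokens
    compare as their stripped text.
    """
    t = token.strip()
    if "_" not in t:
        try:
            f = float(t)
        except ValueError:
            return t
        if math.isfinite(f):
            return format(f, ".12g")
    return t


@dataclass
class MissingCodeSpec:
    """User-defined missing-value codes in force for a submission.

    ``meaning_pattern`` is a case-insensitive regular expression searched
    against value-map meanings; matching entries contribute their code to
    that variable's effective missing set (e.g. ``-9999=missing value``).
    """

    global_codes: set[str] = field(default_factory=lambda: set(DEFAULT_MISSING_CODES))
    per_variable: dict[str, set[str]] = field(default_factory=dict)
    meaning_pattern: str = "missing"

    def effective_codes(self, name: str, var: VariableDefinition | None = None) -> set[str]:
        """Normalised effective missing codes for one variable."""
        out = {normalize_code(c) for c in self.global_codes}
        out |= {normalize_code(c) for c in self.per_variable.get(name, ())}
        if var is not None and self.meaning_pattern:
            pat = re.compile(self.meaning_pattern, re.IGNORECASE)
            entries, _ = var.parsed_values()
            out |= {
                normalize_code(e.code) for e in entries if pat.search(e.meaning)
            }
        return out


@dataclass
class CheckConfig:
    """Panel configuration (all defaults materialised)."""

    codes: MissingCodeSpec = field(default_factory=MissingCodeSpec)
    id_name: str = "SUBJECT_ID"
    na_severity: str = "informational"  # or "fail"
    disabled_checks: set[str] = field(default_factory=set)


@dataclass(frozen=True)
class Finding:
    """One offending item: variable, optional row (1-based data row), value."""

    variable: str | None = None
    row: int | None = None
    value: str | None = None
    note: str = ""

    def to_dict(self) -> dict:
        return {
            "variable": self.variable,
            "row": self.row,
            "value": self.value,
            "note": self.note,
        }


@dataclass
class CheckResult:
    """Outcome of one check.

    ``status`` is pass/fail/not_run; pass iff ``details`` is empty.
    ``info`` holds purely informational findings that never affect status
    (e.g. per-variable missing counts, unrecognised TYPE labels).
    """

    check_name: str
    status: str
    message: str
    details: list[Finding] = field(default_factory=list)
    info: list[Finding] = field(default_factory=list)

    @classmethod
    def from_details(
        cls,
        name: str,
        details: Sequence[Finding],
        pass_msg: str,
        fail_msg: str,
        info: Sequence[Finding] = (),
    ) -> "CheckResult":
        if details:
            return cls(name, "fail", fail_msg, list(details), list(info))
        return cls(name, "pass", pass_msg, [], list(info))

    def to_dict(self) -> dict:
        return {
            "check": self.check_name,
            "status": self.status,
            "message": self.message,
            "details": [f.to_dict() for f in self.details],
            "info": [f.to_dict() for f in self.info],
        }


@dataclass
class CheckReport:
    """The ordered panel outcome; overall pass iff no check failed."""

    results: list[CheckResult] = field(default_factory=list)

    @property
    def overall(self) -> bool:
        return not any(r.status == "fail" for r in self.results)

    def result(self, name: str) -> CheckResult | None:
        for r in self.results:
            if r.check_name == name:
                return r
        return None

    @property
    def failed(self) -> list[str]:
        return [r.check_name for r in self.results if r.status == "fail"]

    @property
    def not_run(self) -> list[str]:
        return [r.check_name for r in self.results if r.status == "not_run"]

    def to_dict(self) -> dict:
        return {
            "overall": "pass" if self.overall else "fail",
            "results": [r.to_dict() for r in self.results],
        }

    def format_table(self) -> str:
        """Fixed-width console rendering."""
        rows = [("CHECK", "STATUS", "MESSAGE")]
        for r in self.results:
            rows.append((r.check_name, r.status.upper(), r.message))
        w0 = max(len(r[0]) for r in rows)
        w1 = max(len(r[1]) for r in rows)
        lines = [f"{r[0]:<{w0}}  {r[1]:<{w1}}  {r[2]}" for r in rows]
        lines.insert(1, "-" * len(lines[0]))
        lines.append(
            f"overall: {'PASS' if self.overall else 'FAIL'}"
            f" ({len(self.failed)} failed, {len(self.not_run)} not run)"
        )
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# alignment helpers

def dictionary_defines_id(ds: PhenotypeDataset, dd: DataDictionary) -> bool:
    low = ds.subject_id_name.lower()
    return any(v.name.lower() == low for v in dd.variables)


def dataset_variable_names(ds: PhenotypeDataset, dd: DataDictionary) -> list[str]:
    """Data-set columns the dictionary is expected to describe.

    Two dictionary dialects occur in practice: the subject-ID column may or
    may not get its own dictionary row.  The ID column is included in the
    comparison exactly when the dictionary defines it.
    """
    return ds.variable_names(include_id=dictionary_defines_id(ds, dd))


def _is_user_missing(cell: Cell, eff_codes: set[str]) -> bool:
    return not cell.is_missing and normalize_code(cell.raw) in eff_codes


# ---------------------------------------------------------------------------
# the twelve checks

def field_check(dd: DataDictionary) -> CheckResult:
    """dbGaP-required dictionary fields VARNAME, VARDESC, UNITS, VALUES."""
    absent = [f for f in REQUIRED_FIELDS if not dd.has_field(f)]
    return CheckResult.from_details(
        "field_check",
        [Finding(value=f, note=f"required field {f} absent") for f in absent],
        "all dbGaP-required dictionary fields present",
        f"missing dbGaP-required dictionary field(s): {', '.join(absent)}",
    )


def pkg_field_check(dd: DataDictionary) -> CheckResult:
    """Package-required fields TYPE, MIN, MAX (enable type/range checks)."""
    absent = [f for f in PKG_REQUIRED_FIELDS if not dd.has_field(f)]
    return CheckResult.from_details(
        "pkg_field_check",
        [Finding(value=f, note=f"package-required field {f} absent") for f in absent],
        "all package-required dictionary fields present",
        f"missing package-required field(s): {', '.join(absent)}"
        " — run add_missing_fields to infer TYPE and add empty MIN/MAX",
    )


def dimension_check(ds: PhenotypeDataset, dd: DataDictionary) -> CheckResult:
    """Variable counts agree between data set and dictionary."""
    n_data = len(dataset_variable_names(ds, dd))
    n_dict = len(dd.variables)
    details = []
    if n_data != n_dict:
        details.append(
            Finding(
                note=f"data set has {n_data} variable columns, dictionary has {n_dict} rows",
                value=f"{n_data} vs {n_dict}",
            )
        )
    return CheckResult.from_details(
        "dimension_check",
        details,
        f"{n_data} variables in both files",
        f"variable counts differ: {n_data} (data set) vs {n_dict} (dictionary)",
    )


def name_check(ds: PhenotypeDataset, dd: DataDictionary) -> CheckResult:
    """Variable names (and their order) agree between the two files."""
    data_names = dataset_variable_names(ds, dd)
    dict_names = dd.variable_names
    only_data = [n for n in data_names if n not in set(dict_names)]
    only_dict = [n for n in dict_names if n not in set(data_names)]
    details = [
        Finding(variable=n, note="in data set but not in dictionary") for n in only_data
    ] + [
        Finding(variable=n, note="in dictionary but not in data set") for n in only_dict
    ]
    if not details and data_names != dict_names:
        details.append(
            Finding(
                note="name sets agree but order differs — run reorder_dictionary",
                value=" ".join(dict_names),
            )
        )
    return CheckResult.from_details(
        "name_check",
        details,
        "variable names and order agree",
        "variable names differ between data set and dictionary",
    )


def id_check(ds: PhenotypeDataset, id_name: str = "SUBJECT_ID") -> CheckResult:
    """Subject-ID column: expected name, complete, unique."""
    details: list[Finding] = []
    if ds.subject_id_name != id_name:
        details.append(
            Finding(
                variable=ds.subject_id_name,
                note=f"first column is {ds.subject_id_name!r}; rename to {id_name!r}",
            )
        )
    seen: dict[str, list[int]] = {}
    for i, cell in enumerate(ds.subject_ids, start=1):
        if cell.is_missing:
            details.append(Finding(variable=ds.subject_id_name, row=i, note="missing subject ID"))
        else:
            seen.setdefault(cell.raw, []).append(i)
    for raw, rows in seen.items():
        if len(rows) > 1:
            details.append(
                Finding(
                    variable=ds.subject_id_name,
                    value=raw,
                    note=f"duplicated subject ID in rows {rows}",
                )
            )
    return CheckResult.from_details(
        "id_check",
        details,
        "subject IDs complete and unique",
        "subject-ID column has problems",
    )


def _empty_row_indices(ds: PhenotypeDataset) -> list[int]:
    out = []
    for i in range(ds.n_rows):
        if all(c.is_missing for c in ds.row(i, include_id=False)):
            out.append(i)
    return out


def row_check(ds: PhenotypeDataset) -> CheckResult:
    """Duplicate or empty participant rows.

    Rows are compared over their non-ID cells: a participant entered twice
    under a fresh ID is the realistic duplication error, and byte-identical
    rows are still caught.
    """
    details: list[Finding] = []
    groups: dict[tuple, list[int]] = {}
    for i in range(ds.n_rows):
        key = tuple(c.raw for c in ds.row(i, include_id=False))
        groups.setdefault(key, []).append(i + 1)
    for rows in groups.values():
        if len(rows) > 1:
            details.append(
                Finding(note=f"rows {rows} have identical phenotype data", value=str(rows))
            )
    for i in _empty_row_indices(ds):
        details.append(Finding(row=i + 1, note="row has no phenotype data (all cells empty)"))
    return CheckResult.from_details(
        "row_check",
        details,
        "no duplicated or empty participant rows",
        "duplicated and/or empty participant rows found",
    )


def na_check(
    ds: PhenotypeDataset,
    dd: DataDictionary,
    codes: MissingCodeSpec | None = None,
    severity: str = "informational",
) -> CheckResult:
    """Consistent encoding of missingness.

    Reports native-missing (empty-cell) counts per variable, and flags
    variables that mix native-missing cells with user-defined missing codes
    — two encodings of the same thing.  Rows with no phenotype data at all
    are excluded (they are row_check's finding, not a per-variable encoding
    inconsistency).  Mixed-encoding findings are informational by default;
    ``severity="fail"`` promotes them to failures.
    """
    codes = codes or MissingCodeSpec()
    skip = set(_empty_row_indices(ds))
    details: list[Finding] = []
    info: list[Finding] = []
    for name in ds.variable_names(include_id=False):
        var = dd.get(name)
        eff = codes.effective_codes(name, var)
        cells = [c for i, c in enumerate(ds.column(name)) if i not in skip]
        n_native = sum(c.is_missing for c in cells)
        n_coded = sum(_is_user_missing(c, eff) for c in cells)
        if n_native:
            info.append(
                Finding(variable=name, value=str(n_native), note=f"{n_native} empty (native-missing) cell(s)")
            )
        if n_native and n_coded:
            f = Finding(
                variable=name,
                note=(
                    f"mixes {n_native} empty cell(s) with {n_coded} user-defined"
                    " missing code cell(s) — inconsistent missingness encoding"
                ),
            )
            (details if severity == "fail" else info).append(f)
    return CheckResult.from_details(
        "na_check",
        details,
        "missingness encoding consistent",
        "variables mix empty cells with user-defined missing codes",
        info=info,
    )


def _collapse(text: str) -> str:
    return " ".join(text.split()).lower()


def description_check(dd: DataDictionary) -> CheckResult:
    """No empty descriptions, no duplicated names or descriptions."""
    details: list[Finding] = []
    for v in dd.variables:
        if not v.description.strip():
            details.append(Finding(variable=v.name, note="empty VARDESC"))
    by_name: dict[str, list[str]] = {}
    by_desc: dict[str, list[str]] = {}
    for v in dd.variables:
        by_name.setdefault(_collapse(v.name), []).append(v.name)
        if v.description.strip():
            by_desc.setdefault(_collapse(v.description), []).append(v.name)
    for names in by_name.values():
        if len(names) > 1:
            details.append(
                Finding(value=names[0], note=f"duplicated VARNAME across rows: {names}")
            )
    for desc, names in by_desc.items():
        if len(names) > 1:
            details.append(
                Finding(
                    value=desc,
                    note=f"variables {names} share the description {desc!r}",
                )
            )
    return CheckResult.from_details(
        "description_check",
        details,
        "variable names and descriptions unique and non-empty",
        "duplicate or empty variable names/descriptions",
    )


# TYPE vocabulary: open set, matched case-insensitively.
_INT_TYPES = {"integer", "int"}
_NUM_TYPES = {"decimal", "num", "numeric", "number", "float", "double"}
_ENC_TYPES = {"encoded", "encoded value", "encoded values", "enumerated integer"}
_STR_TYPES = {"string", "char", "character", "text", "date", "time", "datetime", "year"}


def _type_class(label: str) -> str | None:
    t = " ".join(label.split()).lower()
    if t in _INT_TYPES:
        return "integer"
    if t in _NUM_TYPES:
        return "decimal"
    if t in _ENC_TYPES:
        return "encoded"
    if t in _STR_TYPES:
        return "string"
    return None


def type_check(
    ds: PhenotypeDataset, dd: DataDictionary, codes: MissingCodeSpec | None = None
) -> CheckResult:
    """Observed values are compatible with each variable's declared TYPE.

    Integer admits only integers; decimal admits any number; encoded expects
    integer-like category codes; string admits anything.  Missing cells and
    user-defined missing codes are exempt.  Empty or unrecognised TYPE
    labels yield informational findings (the vocabulary is an open set).
    """
    codes = codes or MissingCodeSpec()
    details: list[Finding] = []
    info: list[Finding] = []
    for v in dd.variables:
        if v.name not in ds.columns:
            continue
        label = v.type.strip()
        if not label:
            info.append(Finding(variable=v.name, note="empty TYPE"))
            continue
        cls = _type_class(label)
        if cls is None:
            info.append(
                Finding(variable=v.name, value=label, note=f"unrecognised TYPE label {label!r}")
            )
            continue
        if cls == "string":
            continue
        eff = codes.effective_codes(v.name, v)
        for i, cell in enumerate(ds.column(v.name), start=1):
            if cell.is_missing or _is_user_missing(cell, eff):
                continue
            val = cell.value
            ok = (
                isinstance(val, int)
                if cls in ("integer", "encoded")
                else isinstance(val, (int, float))
            )
            if not ok:
                details.append(
                    Finding(
                        variable=v.name,
                        row=i,
                        value=cell.raw,
                        note=f"value {cell.raw!r} incompatible with TYPE {label!r}",
                    )
                )
                break  # first offending value per variable
    return CheckResult.from_details(
        "type_check",
        details,
        "observed values compatible with declared types",
        "values incompatible with declared variable types",
        info=info,
    )


def values_check(
    ds: PhenotypeDataset, dd: DataDictionary, codes: MissingCodeSpec | None = None
) -> CheckResult:
    """Value=meaning maps are well-formed and complete.

    Fails on malformed entries and on encoded variables whose observed
    (non-missing) values lack a map entry; map codes never observed in the
    data are reported informationally.
    """
    codes = codes or MissingCodeSpec()
    details: list[Finding] = []
    info: list[Finding] = []
    for v in dd.variables:
        entries, malformed = v.parsed_values()
        for cell in malformed:
            details.append(
                Finding(variable=v.name, value=cell, note=f"malformed value entry {cell!r}")
            )
        if v.name not in ds.columns:
            continue
        eff = codes.effective_codes(v.name, v)
        map_codes = {normalize_code(e.code) for e in entries}
        observed: dict[str, int] = {}
        for i, cell in enumerate(ds.column(v.name), start=1):
            if cell.is_missing or _is_user_missing(cell, eff):
                continue
            observed.setdefault(normalize_code(cell.raw), i)
        if _type_class(v.type) == "encoded":
            for code, first_row in sorted(observed.items()):
                if code not in map_codes:
                    details.append(
                        Finding(
                            variable=v.name,
                            row=first_row,
                            value=code,
                            note=f"observed value {code} has no value=meaning entry",
                        )
                    )
        for e in entries:
            c = normalize_code(e.code)
            if c not in observed and c not in eff:
                info.append(
                    Finding(
                        variable=v.name,
                        value=e.code,
                        note=f"map code {e.code} never observed in the data",
                    )
                )
    return CheckResult.from_details(
        "values_check",
        details,
        "value=meaning maps well-formed and complete",
        "malformed or incomplete value=meaning maps",
        info=info,
    )


def missing_value_check(
    ds: PhenotypeDataset, dd: DataDictionary, codes: MissingCodeSpec | None = None
) -> CheckResult:
    """Every observed missing code is declared in that variable's value map."""
    codes = codes or MissingCodeSpec()
    details: list[Finding] = []
    for v in dd.variables:
        if v.name not in ds.columns:
            continue
        eff = codes.effective_codes(v.name, v)
        entries, _ = v.parsed_values()
        map_codes = {normalize_code(e.code) for e in entries}
        observed_codes: dict[str, int] = {}
        for i, cell in enumerate(ds.column(v.name), start=1):
            if _is_user_missing(cell, eff):
                observed_codes.setdefault(normalize_code(cell.raw), i)
        for code, first_row in sorted(observed_codes.items()):
            if code not in map_codes:
                details.append(
                    Finding(
                        variable=v.name,
                        row=first_row,
                        value=code,
                        note=f"missing code {code} observed but has no value=meaning entry",
                    )
                )
    return CheckResult.from_details(
        "missing_value_check",
        details,
        "all observed missing codes are declared in the value maps",
        "missing codes observed without value=meaning entries",
    )


def minmax_check(
    ds: PhenotypeDataset, dd: DataDictionary, codes: MissingCodeSpec | None = None
) -> CheckResult:
    """Observed values are not more extreme than the logical MIN/MAX.

    Bounds are inclusive.  Cells equal to an effective missing code are
    excluded first; variables with both bounds empty are skipped; a
    non-numeric, non-empty bound is an "unparseable bound" finding.
    """
    codes = codes or MissingCodeSpec()
    details: list[Finding] = []
    for v in dd.variables:
        if v.name not in ds.columns:
            continue
        has_min, has_max = bool(v.min.strip()), bool(v.max.strip())
        if not has_min and not has_max:
            continue
        lo, hi = v.min_value, v.max_value
        bad_bound = False
        for present, value, fieldname, raw in (
            (has_min, lo, "MIN", v.min),
            (has_max, hi, "MAX", v.max),
        ):
            if present and value is None:
                details.append(
                    Finding(
                        variable=v.name,
                        value=raw,
                        note=f"unparseable bound: {fieldname} is {raw!r}",
                    )
                )
                bad_bound = True
        if bad_bound:
            continue
        eff = codes.effective_codes(v.name, v)
        for i, cell in enumerate(ds.column(v.name), start=1):
            if cell.is_missing or _is_user_missing(cell, eff):
                continue
            val = cell.value
            if not isinstance(val, (int, float)):
                continue  # non-numeric text is type_check's finding
            if lo is not None and val < lo:
                details.append(
                    Finding(variable=v.name, row=i, value=cell.raw,
                            note=f"value {cell.raw} below MIN {v.min}")
                )
            elif hi is not None and val > hi:
                details.append(
                    Finding(variable=v.name, row=i, value=cell.raw,
                            note=f"value {cell.raw} above MAX {v.max}")
                )
    return CheckResult.from_details(
        "minmax_check",
        details,
        "all observed values within logical MIN/MAX bounds",
        "values more extreme than the logical MIN/MAX bounds",
    )


# ---------------------------------------------------------------------------
# orchestration

#: Canonical panel order.
PANEL_ORDER = (
    "field_check",
    "pkg_field_check",
    "dimension_check",
    "name_check",
    "id_check",
    "row_check",
    "na_check",
    "description_check",
    "type_check",
    "values_check",
    "missing_value_check",
    "minmax_check",
)

#: check -> prerequisite check that must pass for it to run.
PREREQUISITES = {
    "name_check": "dimension_check",
    "type_check": "pkg_field_check",
    "minmax_check": "pkg_field_check",
    "values_check": "field_check",
    "missing_value_check": "field_check",
}


def check_report(
    ds: PhenotypeDataset,
    dd: DataDictionary,
    codes: MissingCodeSpec | None = None,
    config: CheckConfig | None = None,
) -> CheckReport:
    """Run the full panel in canonical order.

    A check whose prerequisite did not pass (or did not run) is reported as
    ``not_run`` naming the prerequisite.  ``codes`` overrides
    ``config.codes`` when both are given.
    """
    config = config or CheckConfig()
    codes = codes if codes is not None else config.codes

    runners: dict[str, Callable[[], CheckResult]] = {
        "field_check": lambda: field_check(dd),
        "pkg_field_check": lambda: pkg_field_check(dd),
        "dimension_check": lambda: dimension_check(ds, dd),
        "name_check": lambda: name_check(ds, dd),
        "id_check": lambda: id_check(ds, config.id_name),
        "row_check": lambda: row_check(ds),
        "na_check": lambda: na_check(ds, dd, codes, config.na_severity),
        "description_check": lambda: description_check(dd),
        "type_check": lambda: type_check(ds, dd, codes),
        "values_check": lambda: values_check(ds, dd, codes),
        "missing_value_check": lambda: missing_value_check(ds, dd, codes),
        "minmax_check": lambda: minmax_check(ds, dd, codes),
    }

    report = CheckReport()
    status: dict[str, str] = {}
    for name in PANEL_ORDER:
        if name in config.disabled_checks:
            continue
        prereq = PREREQUISITES.get(name)
        if prereq is not None and status.get(prereq) not in (None, "pass"):
            result = CheckResult(
                check_name=name,
                status="not_run",
                message=f"not run: prerequisite {prereq} did not pass",
            )
        elif prereq is not None and prereq in config.disabled_checks:
            result = runners[name]()
        else:
            result = runners[name]()
        status[name] = result.status
        report.results.append(result)
    return report
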