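"""Seedable synthetic fixtures: clean submissions and injected errors.

``generate_clean`` produces a (data set, dictionary) pair that passes the
whole check panel; ``inject_error`` applies exactly one minimal perturbation
of a named kind so each failure can be attributed unambiguously.  The error
taxonomy maps one kind to each check in the panel (``ERROR_CHECK_MAP``),
which makes the diagonal-detection property testable: one injected error,
one failing check.

Determinism: the same (spec, seed) yields byte-identical files on every
platform.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .checks import MissingCodeSpec, normalize_code
from .errors import FixtureSpecError, InjectionError
from .io import (
    Cell,
    DataDictionary,
    PhenotypeDataset,
    VariableDefinition,
)

__all__ = [
    "VariablePlan",
    "FixtureSpec",
    "ERROR_KINDS",
    "ERROR_CHECK_MAP",
    "EXPECTED_NOT_RUN",
    "default_plan",
    "random_spec",
    "generate_clean",
    "inject_error",
]

#: error kind -> the one panel check it must trip.
ERROR_CHECK_MAP = {
    "missing_required_field": "field_check",
    "missing_pkg_field": "pkg_field_check",
    "extra_data_column": "dimension_check",
    "name_mismatch": "name_check",
    "name_order_scramble": "name_check",
    "bad_subject_id": "id_check",
    "duplicate_row": "row_check",
    "empty_row": "row_check",
    "mixed_missing_encoding": "na_check",
    "duplicate_description": "description_check",
    "empty_description": "description_check",
    "type_violation": "type_check",
    "unmapped_encoded_value": "values_check",
    "malformed_value_entry": "values_check",
    "unmapped_missing_code": "missing_value_check",
    "value_above_max": "minmax_check",
    "value_below_min": "minmax_check",
}

ERROR_KINDS = tuple(ERROR_CHECK_MAP)

#: error kind -> checks legitimately reported not_run after injection
#: (their declared prerequisite is the failing check).
EXPECTED_NOT_RUN = {
    "missing_required_field": {"values_check", "missing_value_check"},
    "missing_pkg_field": {"type_check", "minmax_check"},
    "extra_data_column": {"name_check"},
}


@dataclass
class VariablePlan:
    """Plan for one synthetic variable.

    ``kind`` is one of integer, decimal, encoded, string.  ``value_map``
    lists (code, meaning) category entries for encoded variables.  A
    positive ``missing_rate`` replaces that share of cells with
    ``missing_code`` and declares the code in the value map (clean fixtures
    never use empty cells for missingness).
    """

    name: str
    kind: str
    units: str = ""
    min: float | None = None
    max: float | None = None
    value_map: tuple[tuple[str, str], ...] = ()
    categories: tuple[str, ...] = ()
    missing_rate: float = 0.0
    missing_code: str = "-9999"
    description: str = ""


@dataclass
class FixtureSpec:
    """A whole fixture: participant count, variable plans, seed."""

    n_subjects: int = 100
    variables: list[VariablePlan] = field(default_factory=lambda: default_plan())
    seed: int = 42
    subject_id_name: str = "SUBJECT_ID"


def default_plan() -> list[VariablePlan]:
    """The default 12-variable plan: a small cardiovascular-style survey."""
    return [
        VariablePlan("AGE", "integer", "years", 18, 80, missing_rate=0.05,
                     description="Age at enrollment"),
        VariablePlan("HEIGHT", "decimal", "cm", 120, 210, missing_rate=0.05,
                     description="Standing height"),
        VariablePlan("WEIGHT", "decimal", "kg", 35, 200, missing_rate=0.05,
                     description="Body weight"),
        VariablePlan("BMI", "decimal", "kg/m2", 12, 60,
                     description="Body mass index"),
        VariablePlan("SBP", "integer", "mmHg", 80, 250, missing_rate=0.05,
                     description="Systolic blood pressure"),
        VariablePlan("DBP", "integer", "mmHg", 40, 150,
                     description="Diastolic blood pressure"),
        VariablePlan("SEX", "encoded",
                     value_map=(("0", "female"), ("1", "male")),
                     missing_rate=0.02, description="Self-reported sex"),
        VariablePlan("SMOKER", "encoded",
                     value_map=(("0", "no"), ("1", "yes"), ("2", "former")),
                     missing_rate=0.05, description="Smoking status"),
        VariablePlan("DIABETES", "encoded",
                     value_map=(("0", "no"), ("1", "yes")),
                     description="Diabetes diagnosis"),
        VariablePlan("SITE", "string",
                     categories=("A", "B", "C", "D", "E"),
                     description="Enrollment site"),
        VariablePlan("COHORT", "string",
                     categories=("baseline", "followup"),
                     description="Study cohort"),
        VariablePlan("VISIT_YEAR", "integer", "year", 2000, 2020,
                     description="Year of baseline visit"),
    ]


def random_spec(seed: int, max_subjects: int = 60, max_variables: int = 8) -> FixtureSpec:
    """A random but internally consistent fixture spec (for property tests).

    Variable kinds, bounds, category sets and missing rates are drawn at
    random; the result always satisfies :func:`generate_clean`'s
    preconditions.
    """
    rng = np.random.default_rng(seed)
    n_subjects = int(rng.integers(1, max_subjects + 1))
    n_vars = int(rng.integers(1, max_variables + 1))
    # one wide numeric variable guarantees enough joint entropy for
    # generate_clean to draw distinct participant rows
    plans: list[VariablePlan] = [
        VariablePlan("MEASURE0", "integer", "units", 0, 100000,
                     description="Random wide-range integer measurement")
    ]
    for i in range(n_vars):
        kind = ("integer", "decimal", "encoded", "string")[int(rng.integers(4))]
        name = f"V{i + 1}_{kind.upper()[:3]}"
        missing_rate = float(rng.choice([0.0, 0.0, 0.1]))
        if kind in ("integer", "decimal"):
            lo = int(rng.integers(0, 50))
            hi = lo + int(rng.integers(1, 100))
            plans.append(
                VariablePlan(name, kind, "units", lo, hi, missing_rate=missing_rate,
                             description=f"Random {kind} variable {i + 1}")
            )
        elif kind == "encoded":
            k = int(rng.integers(2, 6))
            vm = tuple((str(j), f"level {j}") for j in range(k))
            plans.append(
                VariablePlan(name, kind, value_map=vm, missing_rate=missing_rate,
                             description=f"Random encoded variable {i + 1}")
            )
        else:
            k = int(rng.integers(2, 6))
            cats = tuple(f"cat{j}" for j in range(k))
            plans.append(
                VariablePlan(name, kind, categories=cats,
                             description=f"Random string variable {i + 1}")
            )
    return FixtureSpec(n_subjects=n_subjects, variables=plans, seed=int(rng.integers(2**31)))


def _validate_spec(spec: FixtureSpec) -> None:
    if spec.n_subjects < 1:
        raise FixtureSpecError("n_subjects must be >= 1")
    if not spec.variables:
        raise FixtureSpecError("at least one variable is required")
    names = [v.name for v in spec.variables]
    if len(set(names)) != len(names):
        raise FixtureSpecError("duplicate variable names in spec")
    for v in spec.variables:
        if v.kind not in ("integer", "decimal", "encoded", "string"):
            raise FixtureSpecError(f"{v.name}: unknown kind {v.kind!r}")
        if v.kind in ("integer", "decimal"):
            if v.min is None or v.max is None:
                raise FixtureSpecError(f"{v.name}: numeric kind needs min and max")
            if v.min > v.max:
                raise FixtureSpecError(f"{v.name}: inverted bounds {v.min} > {v.max}")
        if v.kind == "encoded" and not v.value_map:
            raise FixtureSpecError(f"{v.name}: encoded kind needs a value map")
        if v.kind == "string" and not v.categories:
            raise FixtureSpecError(f"{v.name}: string kind needs categories")
        if not 0.0 <= v.missing_rate <= 1.0:
            raise FixtureSpecError(f"{v.name}: missing_rate outside [0, 1]")


_TYPE_LABEL = {
    "integer": "integer",
    "decimal": "decimal",
    "encoded": "encoded value",
    "string": "string",
}


def _fmt_bound(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else str(x)


def generate_clean(spec: FixtureSpec | None = None) -> tuple[PhenotypeDataset, DataDictionary]:
    """Generate a clean fixture pair that passes every panel check.

    Numeric draws stay inside the declared bounds, encoded cells come from
    the value map, and missingness always uses the declared code (never an
    empty cell).  Encoded and string variables carry empty MIN/MAX — bounds
    on category codes are not meaningful.
    """
    spec = spec or FixtureSpec()
    _validate_spec(spec)
    rng = np.random.default_rng(spec.seed)

    def draw(plan: VariablePlan) -> str:
        if plan.missing_rate and rng.random() < plan.missing_rate:
            return plan.missing_code
        if plan.kind == "integer":
            return str(int(rng.integers(int(plan.min), int(plan.max) + 1)))
        if plan.kind == "decimal":
            return f"{rng.uniform(plan.min, plan.max):.1f}"
        if plan.kind == "encoded":
            codes = [c for c, _ in plan.value_map]
            return codes[int(rng.integers(len(codes)))]
        return plan.categories[int(rng.integers(len(plan.categories)))]

    # participant rows are drawn jointly with rejection so no two rows share
    # identical phenotype data (the clean contract: every check must pass)
    rows: list[tuple[str, ...]] = []
    seen: set[tuple[str, ...]] = set()
    for _ in range(spec.n_subjects):
        for _attempt in range(100):
            row = tuple(draw(p) for p in spec.variables)
            if row not in seen:
                break
        else:
            raise FixtureSpecError(
                "variable plan has too little entropy to draw "
                f"{spec.n_subjects} distinct participant rows"
            )
        seen.add(row)
        rows.append(row)

    columns: dict[str, list[str]] = {
        spec.subject_id_name: [f"S{1001 + i}" for i in range(spec.n_subjects)]
    }
    for j, plan in enumerate(spec.variables):
        columns[plan.name] = [row[j] for row in rows]

    variables: list[VariableDefinition] = []
    for plan in spec.variables:
        value_cells = [f"{c}={m}" for c, m in plan.value_map]
        if plan.missing_rate:
            value_cells.append(f"{plan.missing_code}=missing value")
        numeric = plan.kind in ("integer", "decimal")
        variables.append(
            VariableDefinition(
                name=plan.name,
                description=plan.description or f"Synthetic variable {plan.name}",
                units=plan.units,
                type=_TYPE_LABEL[plan.kind],
                min=_fmt_bound(plan.min) if numeric else "",
                max=_fmt_bound(plan.max) if numeric else "",
                value_cells=value_cells,
            )
        )

    ds = PhenotypeDataset.from_raw(spec.subject_id_name, columns)
    dd = DataDictionary(
        variables=variables,
        present_fields=["VARNAME", "VARDESC", "UNITS", "TYPE", "MIN", "MAX", "VALUES"],
    )
    return ds, dd


# ---------------------------------------------------------------------------
# error injection

def _set_cell(ds: PhenotypeDataset, name: str, row: int, raw: str) -> str:
    old = ds.columns[name][row].raw
    ds.columns[name][row] = Cell(raw)
    return old


def _pick(rng: np.random.Generator, items: list):
    if not items:
        raise InjectionError("no applicable target in fixture")
    return items[int(rng.integers(len(items)))]


def inject_error(
    ds: PhenotypeDataset,
    dd: DataDictionary,
    kind: str,
    seed: int = 0,
) -> tuple[PhenotypeDataset, DataDictionary, dict]:
    """Apply exactly one minimal perturbation of the given kind.

    Returns a new (data set, dictionary, manifest) triple; the inputs are
    untouched.  The manifest records the kind, the perturbed location and
    the check expected to fail.  Raises :class:`InjectionError` when the
    kind is not applicable to this fixture (e.g. no encoded variable).
    """
    if kind not in ERROR_CHECK_MAP:
        raise InjectionError(f"unknown error kind {kind!r}")
    ds = copy.deepcopy(ds)
    dd = copy.deepcopy(dd)
    rng = np.random.default_rng(seed)
    codes = MissingCodeSpec()
    manifest: dict = {"kind": kind, "expected_check": ERROR_CHECK_MAP[kind]}
    var_names = ds.variable_names(include_id=False)

    def dd_var(name: str) -> VariableDefinition:
        v = dd.get(name)
        if v is None:
            raise InjectionError(f"{name} not in dictionary")
        return v

    def numeric_vars(kind_label: str) -> list[str]:
        return [
            v.name
            for v in dd.variables
            if v.type == kind_label and v.name in ds.columns
        ]

    def non_code_rows(name: str) -> list[int]:
        eff = codes.effective_codes(name, dd.get(name))
        return [
            i
            for i, c in enumerate(ds.column(name))
            if not c.is_missing and normalize_code(c.raw) not in eff
        ]

    if kind == "missing_required_field":
        dd.present_fields = [f for f in dd.present_fields if f != "UNITS"]
        manifest["field"] = "UNITS"

    elif kind == "missing_pkg_field":
        dd.present_fields = [f for f in dd.present_fields if f != "TYPE"]
        manifest["field"] = "TYPE"

    elif kind == "extra_data_column":
        name = "EXTRA_VAR"
        ds.columns[name] = [
            Cell(str(int(rng.integers(0, 100)))) for _ in range(ds.n_rows)
        ]
        manifest["variable"] = name

    elif kind == "name_mismatch":
        name = _pick(rng, var_names)
        new = name + "_X"
        ds.columns = {
            (new if k == name else k): v for k, v in ds.columns.items()
        }
        manifest.update(variable=name, renamed_to=new)

    elif kind == "name_order_scramble":
        if len(dd.variables) < 2:
            raise InjectionError("need >= 2 dictionary rows to scramble order")
        i = int(rng.integers(len(dd.variables) - 1))
        dd.variables[i], dd.variables[i + 1] = dd.variables[i + 1], dd.variables[i]
        manifest["swapped_rows"] = [i, i + 1]

    elif kind == "bad_subject_id":
        old = ds.subject_id_name
        new = "SUBJ_ID"
        ds.columns = {(new if k == old else k): v for k, v in ds.columns.items()}
        ds.subject_id_name = new
        manifest.update(variable=old, renamed_to=new)

    elif kind == "duplicate_row":
        if ds.n_rows < 2:
            raise InjectionError("need >= 2 rows to duplicate")
        pairs = [
            (i, j)
            for i in range(ds.n_rows)
            for j in range(i + 1, min(i + 20, ds.n_rows))
            if any(
                a.raw != b.raw
                for a, b in zip(ds.row(i, include_id=False), ds.row(j, include_id=False))
            )
        ]
        src, dst = _pick(rng, pairs)
        for name in var_names:
            _set_cell(ds, name, dst, ds.column(name)[src].raw)
        manifest.update(source_row=src + 1, target_row=dst + 1)

    elif kind == "empty_row":
        row = int(rng.integers(ds.n_rows))
        for name in var_names:
            _set_cell(ds, name, row, "")
        manifest["row"] = row + 1

    elif kind == "mixed_missing_encoding":
        candidates = []
        for name in var_names:
            eff = codes.effective_codes(name, dd.get(name))
            col = ds.column(name)
            coded = [i for i, c in enumerate(col)
                     if not c.is_missing and normalize_code(c.raw) in eff]
            plain = [i for i, c in enumerate(col)
                     if not c.is_missing and normalize_code(c.raw) not in eff]
            if coded and plain:
                candidates.append((name, plain))
        name, plain = _pick(rng, candidates)
        row = _pick(rng, plain)
        old = _set_cell(ds, name, row, "")
        manifest.update(variable=name, row=row + 1, original=old)

    elif kind == "duplicate_description":
        if len(dd.variables) < 2:
            raise InjectionError("need >= 2 dictionary rows")
        i, j = sorted(rng.choice(len(dd.variables), size=2, replace=False).tolist())
        dd.variables[j].description = dd.variables[i].description
        manifest.update(variable=dd.variables[j].name, copied_from=dd.variables[i].name)

    elif kind == "empty_description":
        v = _pick(rng, dd.variables)
        manifest.update(variable=v.name, original=v.description)
        v.description = ""

    elif kind == "type_violation":
        names = numeric_vars("integer")
        name = _pick(rng, names)
        v = dd_var(name)
        row = _pick(rng, non_code_rows(name))
        bad = f"{_fmt_bound(v.min_value)}.5" if v.min_value is not None else "0.5"
        old = _set_cell(ds, name, row, bad)
        manifest.update(variable=name, row=row + 1, original=old, value=bad)

    elif kind == "unmapped_encoded_value":
        enc = [v.name for v in dd.variables
               if v.type == "encoded value" and v.name in ds.columns]
        name = _pick(rng, enc)
        v = dd_var(name)
        entries, _ = v.parsed_values()
        codes_int = [int(e.code) for e in entries if e.code.lstrip("+-").isdigit()]
        bad = str(max(c for c in codes_int if c >= 0) + 1) if codes_int else "99"
        row = _pick(rng, non_code_rows(name))
        old = _set_cell(ds, name, row, bad)
        manifest.update(variable=name, row=row + 1, original=old, value=bad)

    elif kind == "malformed_value_entry":
        with_map = [v for v in dd.variables if v.value_cells]
        v = _pick(rng, with_map)
        v.value_cells.append("maybe")
        manifest.update(variable=v.name, value="maybe")

    elif kind == "unmapped_missing_code":
        candidates = []
        for v in dd.variables:
            if v.name not in ds.columns or v.type == "encoded value":
                continue
            entries, _ = v.parsed_values()
            if all(normalize_code(e.code) != normalize_code("-4444") for e in entries):
                candidates.append(v.name)
        name = _pick(rng, candidates)
        row = _pick(rng, non_code_rows(name))
        old = _set_cell(ds, name, row, "-4444")
        manifest.update(variable=name, row=row + 1, original=old, value="-4444")

    elif kind in ("value_above_max", "value_below_min"):
        names = [
            v.name
            for v in dd.variables
            if v.name in ds.columns and v.min_value is not None and v.max_value is not None
        ]
        name = _pick(rng, names)
        v = dd_var(name)
        if kind == "value_above_max":
            bad = _fmt_bound(v.max_value + 1)
            note = "above MAX"
        else:
            bad = _fmt_bound(v.min_value - 1)
            note = "below MIN"
        if normalize_code(bad) in codes.effective_codes(name, v):
            raise InjectionError(f"{name}: out-of-range probe collides with a missing code")
        row = _pick(rng, non_code_rows(name))
        old = _set_cell(ds, name, row, bad)
        manifest.update(variable=name, row=row + 1, original=old, value=bad, note=note)

    return ds, dd, manifest
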