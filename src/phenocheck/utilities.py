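"""Repair helpers and the dictionary-to-data-set metadata merge.

The repairs are pure: inputs are never mutated and a new object is returned.
``label_data`` attaches dictionary metadata (description, units, value
labels, missing codes) to every variable of the data set, with SPSS-style
user-missing semantics: cells equal to a declared missing code are flagged
user-missing, distinct from native-missing empty cells, but their raw value
is retained and recoverable.
"""

from __future__ import annotations

import copy
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from .checks import (
    MissingCodeSpec,
    dataset_variable_names,
    normalize_code,
)
from .errors import AlignmentError
from .io import (
    CANONICAL_FIELDS,
    Cell,
    DataDictionary,
    PhenotypeDataset,
    write_dataset,
)

__all__ = [
    "infer_type",
    "add_missing_fields",
    "reorder_dictionary",
    "VariableMeta",
    "LabelledDataset",
    "label_data",
]


def infer_type(column: list[Cell]) -> str:
    """Infer a TYPE label from observed cells.

    Ignoring native-missing cells: all integers -> "integer"; all numeric
    with at least one non-integer -> "decimal"; anything else -> "string".
    An all-missing column cannot be typed from data and falls back to
    "string" with a warning.

    Never emits "encoded value": category codes are indistinguishable from
    plain integers without investigator intent, so encoded types must be
    refined by hand.
    """
    values = [c.value for c in column if not c.is_missing]
    if not values:
        warnings.warn("all-missing column: TYPE inferred as 'string'", stacklevel=2)
        return "string"
    if all(isinstance(v, int) for v in values):
        return "integer"
    if all(isinstance(v, (int, float)) for v in values):
        return "decimal"
    return "string"


def _insert_field(fields: list[str], name: str) -> list[str]:
    """Insert a canonical field at its canonical position."""
    order = {f: i for i, f in enumerate(CANONICAL_FIELDS)}
    out = list(fields)
    pos = len(out)
    for i, f in enumerate(out):
        if f in order and order[f] > order[name]:
            pos = i
            break
        if f not in order or f == "VALUES":
            pos = i
            break
    out.insert(pos, name)
    return out


def add_missing_fields(dd: DataDictionary, ds: PhenotypeDataset) -> DataDictionary:
    """Add the package-required TYPE/MIN/MAX fields where absent.

    TYPE is inferred from the data per variable; MIN and MAX are added as
    empty columns only — logical bounds can only truly be known by the study
    investigators, so they are never guessed from observed data.  Existing
    non-empty cells are never overwritten.  Returns a new dictionary; the
    input is unmodified.
    """
    out = copy.deepcopy(dd)
    need_type = not out.has_field("TYPE")
    for f in ("TYPE", "MIN", "MAX"):
        if not out.has_field(f):
            out.present_fields = _insert_field(out.present_fields, f)
    if need_type or any(not v.type.strip() for v in out.variables):
        for v in out.variables:
            if v.type.strip():
                continue
            if v.name not in ds.columns:
                raise AlignmentError(
                    f"cannot infer TYPE for {v.name!r}: variable not in the data set",
                    only_in_dictionary=[v.name],
                )
            v.type = infer_type(ds.column(v.name))
    return out


def reorder_dictionary(dd: DataDictionary, ds: PhenotypeDataset) -> DataDictionary:
    """Reorder dictionary rows to match the data set's column order.

    Name sets must already agree; every variable definition is carried over
    untouched.
    """
    expected = dataset_variable_names(ds, dd)
    dict_names = dd.variable_names
    only_ds = [n for n in expected if n not in set(dict_names)]
    only_dd = [n for n in dict_names if n not in set(expected)]
    if only_ds or only_dd:
        raise AlignmentError(
            "cannot reorder: name sets differ "
            f"(only in data set: {only_ds}; only in dictionary: {only_dd})",
            only_in_dataset=only_ds,
            only_in_dictionary=only_dd,
        )
    by_name = {v.name: v for v in dd.variables}
    return DataDictionary(
        variables=[copy.deepcopy(by_name[n]) for n in expected],
        present_fields=list(dd.present_fields),
    )


@dataclass
class VariableMeta:
    """Dictionary metadata carried on one labelled variable."""

    label: str = ""
    units: str = ""
    value_labels: dict[str, str] = field(default_factory=dict)
    missing_codes: set[str] = field(default_factory=set)

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "units": self.units,
            "value_labels": dict(self.value_labels),
            "missing_codes": sorted(self.missing_codes),
        }


@dataclass
class LabelledDataset:
    """A data set with dictionary metadata attached per variable.

    ``user_missing[name][i]`` is True when row *i* of variable *name* holds a
    declared missing code; the raw cell value is untouched, so stripping the
    metadata recovers the original data set exactly.
    """

    base: PhenotypeDataset
    meta: dict[str, VariableMeta]
    user_missing: dict[str, list[bool]]
    source: str = ""

    def strip(self) -> PhenotypeDataset:
        """The underlying data set, structurally equal to the input."""
        return copy.deepcopy(self.base)

    def valid_cells(self, name: str) -> list[Cell]:
        """Cells of a variable excluding native- and user-missing ones."""
        mask = self.user_missing.get(name, [False] * self.base.n_rows)
        return [
            c
            for c, um in zip(self.base.column(name), mask)
            if not um and not c.is_missing
        ]

    def valid_values(self, name: str) -> list:
        return [c.value for c in self.valid_cells(name)]

    def to_dataframe(self):
        """Typed pandas view; user-missing cells become NA.

        Variable metadata travels in ``DataFrame.attrs["variables"]``; raw
        codes remain recoverable from :attr:`base`.
        """
        import pandas as pd

        data = {}
        for name, cells in self.base.columns.items():
            mask = self.user_missing.get(name, [False] * len(cells))
            data[name] = [
                (pd.NA if um or c.is_missing else c.value)
                for c, um in zip(cells, mask)
            ]
        df = pd.DataFrame(data)
        df.attrs["variables"] = {n: m.to_dict() for n, m in self.meta.items()}
        df.attrs["source"] = self.source
        return df

    def export(self, data_path, meta_path) -> None:
        """Write a self-describing bundle: data TSV + JSON metadata sidecar."""
        write_dataset(self.base, data_path)
        payload = {
            "source": self.source,
            "subject_id": self.base.subject_id_name,
            "variables": {n: m.to_dict() for n, m in self.meta.items()},
        }
        Path(meta_path).write_text(
            json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )


def label_data(
    ds: PhenotypeDataset,
    dd: DataDictionary,
    codes: MissingCodeSpec | None = None,
    strict: bool = True,
) -> LabelledDataset:
    """Merge dictionary metadata onto the data set.

    With ``strict=True`` the variable name sets must agree (the subject-ID
    column follows the usual dialect rule); with ``strict=False`` only the
    intersection is labelled — the degraded mode reports use so they work on
    dirty data.
    """
    codes = codes or MissingCodeSpec()
    expected = dataset_variable_names(ds, dd)
    dict_names = dd.variable_names
    only_ds = [n for n in expected if n not in set(dict_names)]
    only_dd = [n for n in dict_names if n not in set(expected)]
    if strict and (only_ds or only_dd):
        raise AlignmentError(
            "cannot label: name sets differ "
            f"(only in data set: {only_ds}; only in dictionary: {only_dd})",
            only_in_dataset=only_ds,
            only_in_dictionary=only_dd,
        )
    meta: dict[str, VariableMeta] = {}
    user_missing: dict[str, list[bool]] = {}
    for v in dd.variables:
        if v.name not in ds.columns:
            continue
        entries, _ = v.parsed_values()
        eff = codes.effective_codes(v.name, v)
        meta[v.name] = VariableMeta(
            label=v.description,
            units=v.units,
            value_labels={e.code: e.meaning for e in entries},
            missing_codes=eff,
        )
        user_missing[v.name] = [
            (not c.is_missing and normalize_code(c.raw) in eff)
            for c in ds.column(v.name)
        ]
    return LabelledDataset(
        base=copy.deepcopy(ds),
        meta=meta,
        user_missing=user_missing,
        source="labelled from data dictionary",
    )
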