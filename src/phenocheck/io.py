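"""Readers and writers for the two-file dbGaP subject phenotype contract.

dbGaP subject phenotype submissions consist of two tab-delimited text files:

* the **data set** — one header row, one row per participant, first column a
  subject identifier, remaining columns phenotype variables;
* the **data dictionary** — one row per variable with the columns VARNAME,
  VARDESC, UNITS, TYPE, MIN, MAX and VALUES, where the VALUES column and any
  columns to its right hold ``code=meaning`` entries (e.g. ``0=no``,
  ``-9999=missing value``), one entry per cell.

This module preserves raw cell text byte-for-byte so that reading a file and
writing it back reproduces it exactly, and so that downstream checks can
report the offending text verbatim.  Recognised dictionary field names are
matched case-insensitively (hand-edited files abound); canonical upper-case
names are emitted on write.  UTF-8 with BOM is tolerated on read, never
written; LF and CRLF line endings are accepted, LF is written.  Tabs are the
only delimiter — there is no quoting dialect, so a tab inside a cell shows up
as a ragged row and is a parse error.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path
from typing import Iterable, Union

from .errors import MalformedValueEntryError, ParseError

__all__ = [
    "CANONICAL_FIELDS",
    "Cell",
    "ValueMapEntry",
    "VariableDefinition",
    "DataDictionary",
    "PhenotypeDataset",
    "parse_scalar",
    "parse_value_entry",
    "read_dictionary",
    "write_dictionary",
    "read_dataset",
    "write_dataset",
]

#: Canonical dictionary fields, in canonical on-disk order.
CANONICAL_FIELDS = ("VARNAME", "VARDESC", "UNITS", "TYPE", "MIN", "MAX", "VALUES")

_INT_RE = re.compile(r"[+-]?\d+\Z")

Scalar = Union[int, float, str, None]


def parse_scalar(text: str) -> Scalar:
    """Type a cell by the narrowest parse: integer, then decimal, then text.

    An empty (or all-whitespace) cell is native-missing and parses to
    ``None``.  Scientific notation parses as decimal.  Tokens that ``float``
    would accept but a curator would not write as numbers ("nan", "inf",
    underscore-grouped digits) stay text.
    """
    t = text.strip()
    if not t:
        return None
    if _INT_RE.fullmatch(t):
        return int(t)
    if "_" not in t:
        try:
            v = float(t)
        except ValueError:
            return t
        if math.isfinite(v):
            return v
    return t


@dataclass(frozen=True)
class Cell:
    """One data-set cell: raw text, with the typed scalar derived lazily."""

    raw: str

    @cached_property
    def value(self) -> Scalar:
        return parse_scalar(self.raw)

    @property
    def is_missing(self) -> bool:
        """True for native-missing (empty) cells."""
        return self.value is None


@dataclass(frozen=True)
class ValueMapEntry:
    """One ``code=meaning`` entry of a variable's value map.

    The code is the exact text left of the first ``=`` (sign and leading
    zeros preserved); the meaning is everything to the right.  Both sides are
    trimmed of surrounding whitespace, so ``0 = no`` and ``0=no`` are the
    same entry.  Meanings may themselves contain ``=``; codes never do.
    """

    code: str
    meaning: str

    def serialize(self) -> str:
        return f"{self.code}={self.meaning}"

    @classmethod
    def parse(cls, text: str) -> "ValueMapEntry":
        if "=" not in text:
            raise MalformedValueEntryError(text, "no '=' present")
        code, meaning = text.split("=", 1)
        code = code.strip()
        if not code:
            raise MalformedValueEntryError(text, "empty code side")
        return cls(code=code, meaning=meaning.strip())


def parse_value_entry(text: str) -> ValueMapEntry:
    """Parse one value=meaning cell; raises :class:`MalformedValueEntryError`."""
    if not text or not text.strip():
        raise MalformedValueEntryError(text, "empty entry")
    return ValueMapEntry.parse(text)


@dataclass
class VariableDefinition:
    """One data-dictionary row.

    ``min``/``max`` keep the raw cell text (possibly empty); the numeric
    views are :attr:`min_value`/:attr:`max_value`.  Value entries are stored
    as raw cells (``value_cells``) so that malformed entries survive lenient
    reads and can be reported by the checks; :attr:`values` is the strict
    parsed view.  ``extras`` holds any unrecognised dictionary columns left
    of VALUES, verbatim and in file order.
    """

    name: str
    description: str = ""
    units: str = ""
    type: str = ""
    min: str = ""
    max: str = ""
    value_cells: list[str] = field(default_factory=list)
    extras: dict[str, str] = field(default_factory=dict)

    @property
    def values(self) -> list[ValueMapEntry]:
        """Parsed value map; raises on any malformed cell."""
        return [ValueMapEntry.parse(c) for c in self.value_cells]

    def parsed_values(self) -> tuple[list[ValueMapEntry], list[str]]:
        """Split value cells into (well-formed entries, malformed raw cells)."""
        good: list[ValueMapEntry] = []
        bad: list[str] = []
        for c in self.value_cells:
            try:
                good.append(ValueMapEntry.parse(c))
            except MalformedValueEntryError:
                bad.append(c)
        return good, bad

    @staticmethod
    def _bound(text: str) -> float | None:
        v = parse_scalar(text)
        if isinstance(v, (int, float)):
            return float(v)
        return None

    @property
    def min_value(self) -> float | None:
        """Numeric logical minimum, or None when empty/unparseable."""
        return self._bound(self.min)

    @property
    def max_value(self) -> float | None:
        """Numeric logical maximum, or None when empty/unparseable."""
        return self._bound(self.max)


@dataclass
class DataDictionary:
    """An ordered collection of variable definitions plus the file's fields.

    ``present_fields`` lists the column names found in the file (canonical
    names upper-cased, extras verbatim), excluding the unnamed spill columns
    right of VALUES.
    """

    variables: list[VariableDefinition] = field(default_factory=list)
    present_fields: list[str] = field(default_factory=list)

    @property
    def variable_names(self) -> list[str]:
        return [v.name for v in self.variables]

    @property
    def extra_fields(self) -> list[str]:
        return [f for f in self.present_fields if f not in CANONICAL_FIELDS]

    def has_field(self, name: str) -> bool:
        return name.upper() in {f.upper() for f in self.present_fields}

    def get(self, name: str) -> VariableDefinition | None:
        for v in self.variables:
            if v.name == name:
                return v
        return None


@dataclass
class PhenotypeDataset:
    """The participant table: ordered columns of cells, subject ID first."""

    subject_id_name: str
    columns: dict[str, list[Cell]]

    def __post_init__(self) -> None:
        names = list(self.columns)
        if names and names[0] != self.subject_id_name:
            raise ValueError("subject_id_name must be the first column")
        lengths = {len(c) for c in self.columns.values()}
        if len(lengths) > 1:
            raise ValueError("columns of unequal length")

    @classmethod
    def from_raw(cls, subject_id_name: str, columns: dict[str, Iterable[str]]) -> "PhenotypeDataset":
        """Build from plain strings (convenience for generators and tests)."""
        return cls(
            subject_id_name=subject_id_name,
            columns={name: [Cell(str(x)) for x in col] for name, col in columns.items()},
        )

    @property
    def n_rows(self) -> int:
        return len(next(iter(self.columns.values()))) if self.columns else 0

    @property
    def subject_ids(self) -> list[Cell]:
        return self.columns[self.subject_id_name]

    def variable_names(self, include_id: bool = False) -> list[str]:
        names = list(self.columns)
        return names if include_id else names[1:]

    def column(self, name: str) -> list[Cell]:
        return self.columns[name]

    def row(self, i: int, include_id: bool = True) -> list[Cell]:
        names = self.variable_names(include_id=include_id)
        return [self.columns[n][i] for n in names]

    def to_dataframe(self):
        """Typed pandas view (parsed scalars; native-missing becomes NA)."""
        import pandas as pd

        data = {
            name: [c.value for c in cells] for name, cells in self.columns.items()
        }
        return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# file I/O

def _read_lines(path) -> list[str]:
    text = Path(path).read_text(encoding="utf-8-sig")
    lines = text.split("\n")
    lines = [ln[:-1] if ln.endswith("\r") else ln for ln in lines]
    if lines and lines[-1] == "":
        lines.pop()
    return lines


def read_dictionary(path, strict: bool = True) -> DataDictionary:
    """Read a data dictionary.

    The VALUES column and every column to its right are consumed
    left-to-right as value entries, skipping empty cells, regardless of the
    spill columns' header text.  With ``strict=True`` (default) a non-empty
    malformed entry is a parse error naming the row and cell; with
    ``strict=False`` the raw cell is kept so the checks panel can report it.
    """
    lines = _read_lines(path)
    if not lines:
        raise ParseError(f"{path}: empty file")
    header = [h.strip() for h in lines[0].split("\t")]
    upper = [h.upper() for h in header]
    values_idx = upper.index("VALUES") if "VALUES" in upper else None

    present_fields: list[str] = []
    roles: list[str] = []  # canonical/extra name per column left of / at VALUES
    for i, h in enumerate(header):
        if values_idx is not None and i > values_idx:
            continue  # spill column, not a named field
        name = h.upper() if h.upper() in CANONICAL_FIELDS else h
        if name in present_fields:
            raise ParseError(f"{path}: duplicate header name {name!r}")
        present_fields.append(name)
        roles.append(name)

    variables: list[VariableDefinition] = []
    width = len(header)
    for lineno, line in enumerate(lines[1:], start=2):
        cells = line.split("\t")
        if len(cells) > width and values_idx is None:
            raise ParseError(
                f"{path}: line {lineno}: {len(cells)} fields but header has {width}"
            )
        if len(cells) < width:
            cells = cells + [""] * (width - len(cells))
        fields_map: dict[str, str] = {}
        value_cells: list[str] = []
        for i, cell in enumerate(cells):
            if values_idx is not None and i >= values_idx:
                c = cell.strip()
                if c:
                    if strict:
                        try:
                            ValueMapEntry.parse(c)
                        except MalformedValueEntryError as exc:
                            raise ParseError(
                                f"{path}: line {lineno}: {exc}"
                            ) from exc
                    value_cells.append(c)
            else:
                fields_map[roles[i]] = cell
        extras = {
            k: v for k, v in fields_map.items() if k not in CANONICAL_FIELDS
        }
        variables.append(
            VariableDefinition(
                name=fields_map.get("VARNAME", "").strip(),
                description=fields_map.get("VARDESC", ""),
                units=fields_map.get("UNITS", ""),
                type=fields_map.get("TYPE", ""),
                min=fields_map.get("MIN", ""),
                max=fields_map.get("MAX", ""),
                value_cells=value_cells,
                extras=extras,
            )
        )
    return DataDictionary(variables=variables, present_fields=present_fields)


def write_dictionary(dd: DataDictionary, path) -> None:
    """Write a data dictionary in canonical field order.

    Canonical fields present in the dictionary come first (VARNAME, VARDESC,
    UNITS, TYPE, MIN, MAX), then extra columns, then VALUES, then one
    unnamed column per additional value entry beyond the first (dbGaP's
    spill-column layout).
    """
    canon = [f for f in CANONICAL_FIELDS[:-1] if dd.has_field(f)]
    extras = dd.extra_fields
    has_values = dd.has_field("VALUES")
    n_spill = 0
    if has_values and dd.variables:
        n_spill = max(0, max(len(v.value_cells) for v in dd.variables) - 1)

    header = canon + extras
    if has_values:
        header += ["VALUES"] + [""] * n_spill

    out_lines = ["\t".join(header)]
    attr = {
        "VARNAME": "name",
        "VARDESC": "description",
        "UNITS": "units",
        "TYPE": "type",
        "MIN": "min",
        "MAX": "max",
    }
    for v in dd.variables:
        row = [getattr(v, attr[f]) for f in canon]
        row += [v.extras.get(e, "") for e in extras]
        if has_values:
            row += v.value_cells + [""] * (1 + n_spill - len(v.value_cells))
        out_lines.append("\t".join(row))
    Path(path).write_text("\n".join(out_lines) + "\n", encoding="utf-8")


def read_dataset(path) -> PhenotypeDataset:
    """Read a subject phenotype data set (>=2 columns, >=1 data row)."""
    lines = _read_lines(path)
    if len(lines) < 2:
        raise ParseError(f"{path}: need a header row and at least one data row")
    header = [h.strip() for h in lines[0].split("\t")]
    if len(header) < 2:
        raise ParseError(f"{path}: need a subject-ID column and at least one variable")
    if len(set(header)) != len(header):
        dupes = sorted({h for h in header if header.count(h) > 1})
        raise ParseError(f"{path}: duplicate column names {dupes}")
    columns: dict[str, list[Cell]] = {h: [] for h in header}
    for lineno, line in enumerate(lines[1:], start=2):
        cells = line.split("\t")
        if len(cells) != len(header):
            raise ParseError(
                f"{path}: line {lineno}: {len(cells)} fields but header has {len(header)}"
            )
        for h, c in zip(header, cells):
            columns[h].append(Cell(c))
    return PhenotypeDataset(subject_id_name=header[0], columns=columns)


def write_dataset(ds: PhenotypeDataset, path) -> None:
    """Write a data set; raw cell text is emitted verbatim."""
    names = list(ds.columns)
    out_lines = ["\t".join(names)]
    for i in range(ds.n_rows):
        out_lines.append("\t".join(ds.columns[n][i].raw for n in names))
    Path(path).write_text("\n".join(out_lines) + "\n", encoding="utf-8")
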