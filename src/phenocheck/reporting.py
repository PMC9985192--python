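"""Human-readable reports: per-variable descriptives and awareness tables.

``create_report`` renders one summary section per dictionary variable —
counts of observed / native-missing / per-code cells, descriptive statistics
for numeric variables, labelled frequency tables for encoded and string
variables, and a figure (histogram with MIN/MAX reference lines, or a
labelled bar chart).  ``create_awareness_report`` surfaces missing-code
usage and value-map completeness for human review; it is purely
informational with no pass/fail verdicts.

Reports are diagnostic documents: they must succeed on dirty data, so by
default variable-name mismatches between the two files degrade to a note
rather than an error.  Rendering is deterministic — identical inputs plus a
pinned timestamp give byte-identical output.
"""

from __future__ import annotations

import base64
import datetime
import html as _html
import io as _stdio
import math
import statistics
from dataclasses import dataclass, field
from pathlib import Path

from matplotlib.backends.backend_agg import FigureCanvasAgg
from matplotlib.figure import Figure as MplFigure

from .checks import MissingCodeSpec, dataset_variable_names, normalize_code
from .errors import AlignmentError, PhenocheckError
from .io import DataDictionary, PhenotypeDataset, VariableDefinition

__all__ = [
    "VariableSummary",
    "Table",
    "ReportFigure",
    "Section",
    "ReportDocument",
    "summarize_variable",
    "create_report",
    "create_awareness_report",
    "render",
]

#: Cap on distinct string values shown in full; beyond it, top 20 + other.
MAX_DISTINCT_FULL = 50
TOP_N = 20


@dataclass
class VariableSummary:
    """Descriptive summary of one variable.

    Counting identity: ``n_observed + n_native_missing + sum(code_counts
    .values()) == n_total``.
    """

    name: str
    declared_type: str
    n_total: int
    n_observed: int
    n_native_missing: int
    code_counts: dict[str, int] = field(default_factory=dict)
    stats: dict[str, float] | None = None
    frequencies: list[tuple[str, int]] | None = None
    notes: list[str] = field(default_factory=list)


@dataclass
class Table:
    header: list[str]
    rows: list[list[str]]
    caption: str = ""


@dataclass
class ReportFigure:
    name: str
    png: bytes
    caption: str = ""


@dataclass
class Section:
    heading: str
    paragraphs: list[str] = field(default_factory=list)
    tables: list[Table] = field(default_factory=list)
    figures: list[ReportFigure] = field(default_factory=list)


@dataclass
class ReportDocument:
    """An ordered report; deterministic given inputs and a fixed timestamp."""

    title: str
    timestamp: str
    inputs: list[str] = field(default_factory=list)
    sections: list[Section] = field(default_factory=list)


def _timestamp(override: str | None) -> str:
    if override is not None:
        return override
    return datetime.datetime.now().isoformat(timespec="seconds")


# ---------------------------------------------------------------------------
# summaries

def summarize_variable(
    ds: PhenotypeDataset,
    var: VariableDefinition,
    codes: MissingCodeSpec | None = None,
) -> VariableSummary:
    """Count and describe one variable's cells.

    Valid values exclude native-missing cells and cells equal to an
    effective missing code; statistics are computed over the numeric subset
    of valid values, frequencies over all valid values.
    """
    codes = codes or MissingCodeSpec()
    cells = ds.column(var.name)
    eff = codes.effective_codes(var.name, var)
    entries, malformed = var.parsed_values()
    labels = {normalize_code(e.code): e.meaning for e in entries}

    code_counts: dict[str, int] = {}
    n_native = 0
    valid = []
    for c in cells:
        if c.is_missing:
            n_native += 1
            continue
        norm = normalize_code(c.raw)
        if norm in eff:
            code_counts[norm] = code_counts.get(norm, 0) + 1
        else:
            valid.append(c)

    summary = VariableSummary(
        name=var.name,
        declared_type=var.type,
        n_total=len(cells),
        n_observed=len(valid),
        n_native_missing=n_native,
        code_counts=code_counts,
    )
    if malformed:
        summary.notes.append(f"{len(malformed)} malformed value entry(ies) in dictionary")
    if not valid:
        summary.notes.append("no valid observations")
        return summary

    numeric = [c.value for c in valid if isinstance(c.value, (int, float))]
    kind = " ".join(var.type.split()).lower()
    is_numeric = kind in ("integer", "int", "decimal", "num", "numeric", "number",
                          "float", "double") or (not kind and len(numeric) == len(valid))
    if is_numeric and numeric:
        summary.stats = {
            "min": float(min(numeric)),
            "mean": float(statistics.fmean(numeric)),
            "median": float(statistics.median(numeric)),
            "max": float(max(numeric)),
        }
        if len(numeric) != len(valid):
            summary.notes.append(
                f"{len(valid) - len(numeric)} non-numeric value(s) excluded from statistics"
            )
    else:
        counts: dict[str, int] = {}
        for c in valid:
            counts[c.raw.strip()] = counts.get(c.raw.strip(), 0) + 1
        items = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        if len(items) > MAX_DISTINCT_FULL:
            top = items[:TOP_N]
            other = sum(n for _, n in items[TOP_N:])
            items = top + [(f"(other: {len(counts) - TOP_N} values)", other)]
            summary.notes.append(f"{len(counts)} distinct values; showing top {TOP_N}")
        summary.frequencies = [
            (f"{val} ({labels[normalize_code(val)]})" if normalize_code(val) in labels else val, n)
            for val, n in items
        ]
    return summary


# ---------------------------------------------------------------------------
# figures

def _fig_to_png(fig: MplFigure) -> bytes:
    canvas = FigureCanvasAgg(fig)
    buf = _stdio.BytesIO()
    canvas.print_png(buf, metadata={"Software": "phenocheck"})
    return buf.getvalue()


def _sturges_bins(values: list[float], integer: bool) -> list[float]:
    n = len(values)
    k = max(1, math.ceil(math.log2(n)) + 1) if n > 1 else 1
    lo, hi = min(values), max(values)
    if integer:
        lo_i, hi_i = int(math.floor(lo)), int(math.ceil(hi))
        width = max(1, math.ceil((hi_i - lo_i + 1) / k))
        edges = [lo_i - 0.5 + i * width for i in range(k + 1)]
        while edges[-1] < hi_i + 0.5:
            edges.append(edges[-1] + width)
        return edges
    if hi == lo:
        return [lo - 0.5, hi + 0.5]
    step = (hi - lo) / k
    return [lo + i * step for i in range(k + 1)]


def _histogram(var: VariableDefinition, values: list[float]) -> bytes:
    integer = all(float(v).is_integer() for v in values)
    fig = MplFigure(figsize=(5, 3))
    ax = fig.add_subplot(111)
    ax.hist(values, bins=_sturges_bins(values, integer), color="#4878a8", edgecolor="white")
    for bound, style in ((var.min_value, "MIN"), (var.max_value, "MAX")):
        if bound is not None:
            ax.axvline(bound, color="#a84848", linestyle="--", linewidth=1)
            ax.text(bound, ax.get_ylim()[1], style, ha="center", va="bottom", fontsize=8)
    ax.set_xlabel(f"{var.name}" + (f" ({var.units})" if var.units.strip() else ""))
    ax.set_ylabel("count")
    fig.tight_layout()
    return _fig_to_png(fig)


def _barchart(name: str, frequencies: list[tuple[str, int]]) -> bytes:
    fig = MplFigure(figsize=(5, 3))
    ax = fig.add_subplot(111)
    labels = [lab for lab, _ in frequencies]
    counts = [n for _, n in frequencies]
    ax.barh(range(len(labels))[::-1], counts, color="#4878a8")
    ax.set_yticks(range(len(labels))[::-1])
    ax.set_yticklabels(labels, fontsize=8)
    ax.set_xlabel("count")
    ax.set_title(name, fontsize=10)
    fig.tight_layout()
    return _fig_to_png(fig)


# ---------------------------------------------------------------------------
# reports

def _aligned_variables(
    ds: PhenotypeDataset, dd: DataDictionary, strict: bool
) -> tuple[list[VariableDefinition], list[str]]:
    expected = dataset_variable_names(ds, dd)
    dict_names = dd.variable_names
    only_ds = [n for n in expected if n not in set(dict_names)]
    only_dd = [n for n in dict_names if n not in set(expected)]
    if strict and (only_ds or only_dd):
        raise AlignmentError(
            f"variable names differ (only in data set: {only_ds}; "
            f"only in dictionary: {only_dd})",
            only_in_dataset=only_ds,
            only_in_dictionary=only_dd,
        )
    notes = []
    if only_ds:
        notes.append("In data set but not in dictionary (not summarised): " + ", ".join(only_ds))
    if only_dd:
        notes.append("In dictionary but not in data set (not summarised): " + ", ".join(only_dd))
    usable = [v for v in dd.variables if v.name in ds.columns]
    return usable, notes


def _summary_table(s: VariableSummary) -> Table:
    rows = [
        ["participants", str(s.n_total)],
        ["valid observations", str(s.n_observed)],
        ["native-missing (empty)", str(s.n_native_missing)],
    ]
    for code in sorted(s.code_counts):
        rows.append([f"missing code {code}", str(s.code_counts[code])])
    if s.stats:
        for k in ("min", "mean", "median", "max"):
            rows.append([k, f"{s.stats[k]:g}"])
    return Table(header=["quantity", "value"], rows=rows)


def create_report(
    ds: PhenotypeDataset,
    dd: DataDictionary,
    codes: MissingCodeSpec | None = None,
    timestamp: str | None = None,
    inputs: list[str] | None = None,
    with_figures: bool = True,
    strict: bool = False,
) -> ReportDocument:
    """Per-variable descriptive report with embedded graphics.

    One section per dictionary variable found in the data set: the counting
    table, then either numeric statistics and a histogram (valid values
    only, user-missing codes excluded; MIN/MAX drawn as reference lines) or
    a labelled frequency table and bar chart.  With ``strict=True`` a
    variable-name mismatch raises; by default it is reported in a note so
    the report works on dirty data.
    """
    codes = codes or MissingCodeSpec()
    usable, align_notes = _aligned_variables(ds, dd, strict)
    doc = ReportDocument(
        title="Subject phenotype data report",
        timestamp=_timestamp(timestamp),
        inputs=list(inputs or []),
    )
    if align_notes:
        doc.sections.append(Section(heading="Alignment notes", paragraphs=align_notes))
    for var in usable:
        s = summarize_variable(ds, var, codes)
        section = Section(heading=f"{var.name}")
        desc = var.description.strip() or "(no description)"
        meta = f"{desc} — type: {var.type.strip() or '(none)'}"
        if var.units.strip():
            meta += f", units: {var.units.strip()}"
        section.paragraphs.append(meta)
        section.tables.append(_summary_table(s))
        for note in s.notes:
            section.paragraphs.append(f"Note: {note}")
        if s.frequencies:
            section.tables.append(
                Table(header=["value", "count"],
                      rows=[[lab, str(n)] for lab, n in s.frequencies],
                      caption="frequency of valid values")
            )
        if with_figures and s.n_observed > 0:
            if s.stats is not None:
                values = [
                    c.value
                    for c in ds.column(var.name)
                    if not c.is_missing
                    and normalize_code(c.raw) not in codes.effective_codes(var.name, var)
                    and isinstance(c.value, (int, float))
                ]
                if values:
                    section.figures.append(
                        ReportFigure(
                            name=f"{var.name}_hist",
                            png=_histogram(var, values),
                            caption=f"Distribution of valid {var.name} values",
                        )
                    )
            elif s.frequencies:
                section.figures.append(
                    ReportFigure(
                        name=f"{var.name}_freq",
                        png=_barchart(var.name, s.frequencies),
                        caption=f"Frequencies of valid {var.name} values",
                    )
                )
        doc.sections.append(section)
    return doc


def create_awareness_report(
    ds: PhenotypeDataset,
    dd: DataDictionary,
    codes: MissingCodeSpec | None = None,
    timestamp: str | None = None,
    inputs: list[str] | None = None,
) -> ReportDocument:
    """Missing-code and value-map awareness tables (informational only).

    Table A: per variable and missing code, the observed count and whether
    the code has a value=meaning entry.  Table B: encoded variables
    observing values absent from their map.  Table C: variables mixing
    native-missing cells with missing codes.
    """
    codes = codes or MissingCodeSpec()
    doc = ReportDocument(
        title="Missing-code and value-map awareness report",
        timestamp=_timestamp(timestamp),
        inputs=list(inputs or []),
    )

    rows_a: list[list[str]] = []
    rows_b: list[list[str]] = []
    rows_c: list[list[str]] = []
    for name in ds.variable_names(include_id=False):
        var = dd.get(name)
        eff = codes.effective_codes(name, var)
        entries = var.parsed_values()[0] if var is not None else []
        map_codes = {normalize_code(e.code) for e in entries}
        counts: dict[str, int] = {}
        n_native = 0
        observed_valid: set[str] = set()
        for c in ds.column(name):
            if c.is_missing:
                n_native += 1
                continue
            norm = normalize_code(c.raw)
            if norm in eff:
                counts[norm] = counts.get(norm, 0) + 1
            else:
                observed_valid.add(norm)
        for code in sorted(counts):
            rows_a.append(
                [name, code, str(counts[code]),
                 "mapped" if code in map_codes else "NOT MAPPED"]
            )
        if var is not None and " ".join(var.type.split()).lower() in (
            "encoded", "encoded value", "encoded values"
        ):
            for v in sorted(observed_valid - map_codes):
                rows_b.append([name, v])
        if counts and n_native:
            rows_c.append([name, str(n_native), str(sum(counts.values()))])

    sec_a = Section(heading="A. Missing-code usage by variable")
    if rows_a:
        sec_a.tables.append(
            Table(header=["variable", "code", "observed count", "value map"], rows=rows_a)
        )
    else:
        sec_a.paragraphs.append("No user-defined missing codes observed in the data.")
    sec_b = Section(heading="B. Encoded values absent from the value map")
    if rows_b:
        sec_b.tables.append(Table(header=["variable", "unmapped value"], rows=rows_b))
    else:
        sec_b.paragraphs.append("Every observed encoded value has a value=meaning entry.")
    sec_c = Section(heading="C. Variables mixing empty cells and missing codes")
    if rows_c:
        sec_c.tables.append(
            Table(header=["variable", "empty cells", "coded missing cells"], rows=rows_c)
        )
    else:
        sec_c.paragraphs.append("No variable mixes empty cells with user-defined missing codes.")
    doc.sections += [sec_a, sec_b, sec_c]
    return doc


# ---------------------------------------------------------------------------
# rendering

def _md_escape(text: str) -> str:
    return text.replace("|", "\\|")


def _md_table(t: Table) -> list[str]:
    lines = []
    if t.caption:
        lines.append(f"*{_md_escape(t.caption)}*")
        lines.append("")
    lines.append("| " + " | ".join(_md_escape(h) for h in t.header) + " |")
    lines.append("|" + "|".join(" --- " for _ in t.header) + "|")
    for row in t.rows:
        lines.append("| " + " | ".join(_md_escape(c) for c in row) + " |")
    lines.append("")
    return lines


def render(doc: ReportDocument, format: str, path) -> Path:
    """Write the document as GitHub-flavoured markdown or standalone HTML.

    Markdown places figures as PNG files in a sibling ``<stem>_files``
    directory and links them relatively; HTML embeds figures base64-inline
    so the file opens standalone.  Re-rendering identical inputs with a
    pinned timestamp is byte-identical.
    """
    path = Path(path)
    if format in ("md", "markdown"):
        lines = [f"# {doc.title}", ""]
        lines.append(f"Generated: {doc.timestamp}")
        if doc.inputs:
            lines.append(f"Inputs: {', '.join(doc.inputs)}")
        lines.append("")
        asset_dir = path.parent / f"{path.stem}_files"
        wrote_assets = False
        for sec in doc.sections:
            lines.append(f"## {sec.heading}")
            lines.append("")
            for p in sec.paragraphs:
                lines.append(p)
                lines.append("")
            for t in sec.tables:
                lines += _md_table(t)
            for fig in sec.figures:
                if not wrote_assets:
                    asset_dir.mkdir(parents=True, exist_ok=True)
                    wrote_assets = True
                (asset_dir / f"{fig.name}.png").write_bytes(fig.png)
                lines.append(f"![{fig.caption}]({asset_dir.name}/{fig.name}.png)")
                lines.append("")
        path.write_text("\n".join(lines), encoding="utf-8")
        return path

    if format == "html":
        e = _html.escape
        parts = [
            "<!DOCTYPE html>",
            "<html><head><meta charset='utf-8'>",
            f"<title>{e(doc.title)}</title>",
            "<style>body{font-family:sans-serif;max-width:60em;margin:auto;padding:1em}"
            "table{border-collapse:collapse;margin:0.5em 0}"
            "td,th{border:1px solid #999;padding:2px 8px;text-align:left}</style>",
            "</head><body>",
            f"<h1>{e(doc.title)}</h1>",
            f"<p>Generated: {e(doc.timestamp)}</p>",
        ]
        if doc.inputs:
            parts.append(f"<p>Inputs: {e(', '.join(doc.inputs))}</p>")
        for sec in doc.sections:
            parts.append(f"<h2>{e(sec.heading)}</h2>")
            for p in sec.paragraphs:
                parts.append(f"<p>{e(p)}</p>")
            for t in sec.tables:
                if t.caption:
                    parts.append(f"<p><em>{e(t.caption)}</em></p>")
                parts.append("<table><tr>" + "".join(f"<th>{e(h)}</th>" for h in t.header) + "</tr>")
                for row in t.rows:
                    parts.append("<tr>" + "".join(f"<td>{e(c)}</td>" for c in row) + "</tr>")
                parts.append("</table>")
            for fig in sec.figures:
                b64 = base64.b64encode(fig.png).decode("ascii")
                parts.append(
                    f"<figure><img src='data:image/png;base64,{b64}' alt='{e(fig.caption)}'>"
                    f"<figcaption>{e(fig.caption)}</figcaption></figure>"
                )
        parts.append("</body></html>")
        path.write_text("\n".join(parts), encoding="utf-8")
        return path

    raise PhenocheckError(f"unknown report format {format!r} (expected 'md' or 'html')")
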