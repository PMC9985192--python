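"""Descriptive and awareness reports: counting identity, determinism, robustness."""

import statistics

import pytest

from phenocheck import (
    AlignmentError,
    create_awareness_report,
    create_report,
    render,
)
from phenocheck.checks import normalize_code
from phenocheck.fixtures import ERROR_KINDS, generate_clean, inject_error, random_spec
from phenocheck.io import PhenotypeDataset, VariableDefinition
from phenocheck.reporting import summarize_variable

TS = "2026-01-01T00:00:00"


class TestVariableSummary:
    @pytest.mark.parametrize("seed", range(8))
    def test_counting_identity(self, seed):
        ds, dd = generate_clean(random_spec(seed))
        for var in dd.variables:
            s = summarize_variable(ds, var)
            assert s.n_observed + s.n_native_missing + sum(s.code_counts.values()) == s.n_total
            assert s.n_total == ds.n_rows

    def test_code_counts_and_stats_match_direct_count(self, clean_pair):
        ds, dd = clean_pair
        var = dd.get("AGE")
        s = summarize_variable(ds, var)
        raws = [c.raw for c in ds.column("AGE")]
        n_code = sum(r == "-9999" for r in raws)
        assert s.code_counts == ({"-9999": n_code} if n_code else {})
        assert s.n_observed == len(raws) - n_code
        valid = [int(r) for r in raws if r != "-9999"]
        assert s.stats == {
            "min": float(min(valid)),
            "mean": float(statistics.fmean(valid)),
            "median": float(statistics.median(valid)),
            "max": float(max(valid)),
        }

    def test_encoded_frequencies_are_labelled(self, clean_pair):
        ds, dd = clean_pair
        s = summarize_variable(ds, dd.get("SEX"))
        labels = dict(s.frequencies)
        assert "0 (female)" in labels and "1 (male)" in labels

    def test_all_missing_variable_degenerates_gracefully(self):
        ds = PhenotypeDataset.from_raw(
            "SUBJECT_ID", {"SUBJECT_ID": ["S1", "S2"], "X": ["", ""]}
        )
        s = summarize_variable(ds, VariableDefinition(name="X", type="integer"))
        assert s.n_observed == 0
        assert s.stats is None and s.frequencies is None
        assert any("no valid observations" in n for n in s.notes)

    def test_many_distinct_strings_truncated_to_top20(self):
        vals = [f"id{i:03d}" for i in range(60)]
        ds = PhenotypeDataset.from_raw(
            "SUBJECT_ID",
            {"SUBJECT_ID": [f"S{i}" for i in range(60)], "X": vals},
        )
        s = summarize_variable(ds, VariableDefinition(name="X", type="string"))
        assert len(s.frequencies) == 21
        assert s.frequencies[-1][1] == 40  # the "other" bucket


class TestCreateReport:
    def test_one_section_per_variable(self, clean_pair):
        doc = create_report(*clean_pair, timestamp=TS)
        headings = [s.heading for s in doc.sections]
        assert headings == clean_pair[0].variable_names()
        assert len(headings) == 12

    def test_numeric_sections_have_histograms(self, clean_pair):
        doc = create_report(*clean_pair, timestamp=TS)
        by_heading = {s.heading: s for s in doc.sections}
        assert by_heading["AGE"].figures[0].name == "AGE_hist"
        assert by_heading["AGE"].figures[0].png.startswith(b"\x89PNG")
        assert by_heading["SEX"].figures[0].name == "SEX_freq"

    def test_strict_mode_raises_on_name_mismatch(self, clean_pair):
        ds, dd = clean_pair
        ds2, dd2, _ = inject_error(ds, dd, "name_mismatch", seed=1)
        with pytest.raises(AlignmentError):
            create_report(ds2, dd2, strict=True)
        doc = create_report(ds2, dd2, timestamp=TS)
        assert doc.sections[0].heading == "Alignment notes"


class TestAwarenessReport:
    def test_table_a_counts_and_mapping(self, clean_pair):
        ds, dd = clean_pair
        doc = create_awareness_report(ds, dd, timestamp=TS)
        table_a = doc.sections[0].tables[0]
        rows = {r[0]: r for r in table_a.rows}
        n = sum(c.raw == "-9999" for c in ds.column("AGE"))
        assert rows["AGE"] == ["AGE", "-9999", str(n), "mapped"]

    def test_unmapped_code_flagged(self, clean_pair):
        ds, dd, _ = inject_error(*clean_pair, "unmapped_missing_code", seed=2)
        doc = create_awareness_report(ds, dd, timestamp=TS)
        flags = [r for r in doc.sections[0].tables[0].rows if r[1] == "-4444"]
        assert flags and flags[0][3] == "NOT MAPPED"

    def test_table_b_unmapped_encoded_value(self, clean_pair):
        ds, dd, man = inject_error(*clean_pair, "unmapped_encoded_value", seed=2)
        doc = create_awareness_report(ds, dd, timestamp=TS)
        sec_b = doc.sections[1]
        assert [man["variable"], normalize_code(man["value"])] in sec_b.tables[0].rows

    def test_empty_tables_get_explanatory_notes(self):
        ds = PhenotypeDataset.from_raw(
            "SUBJECT_ID", {"SUBJECT_ID": ["S1"], "X": ["1"]}
        )
        from phenocheck import DataDictionary

        dd = DataDictionary(
            variables=[VariableDefinition(name="X", description="x", type="integer")],
            present_fields=["VARNAME", "VARDESC", "UNITS", "TYPE", "MIN", "MAX", "VALUES"],
        )
        doc = create_awareness_report(ds, dd, timestamp=TS)
        assert "No user-defined missing codes" in doc.sections[0].paragraphs[0]


class TestRender:
    def test_markdown_pipe_tables_and_linked_figures(self, clean_pair, tmp_path):
        doc = create_report(*clean_pair, timestamp=TS)
        out = render(doc, "md", tmp_path / "report.md")
        text = out.read_text()
        assert text.count("## AGE\n") == 1
        assert "| quantity | value |" in text
        assert "(report_files/AGE_hist.png)" in text
        assert (tmp_path / "report_files" / "AGE_hist.png").exists()

    def test_html_is_standalone(self, clean_pair, tmp_path):
        doc = create_report(*clean_pair, timestamp=TS)
        out = render(doc, "html", tmp_path / "report.html")
        text = out.read_text()
        assert "data:image/png;base64," in text
        assert "src='http" not in text and 'src="http' not in text

    def test_pinned_timestamp_renders_byte_identical(self, clean_pair, tmp_path):
        for run in ("r1", "r2"):
            doc = create_report(*clean_pair, timestamp=TS)
            (tmp_path / run).mkdir()
            render(doc, "html", tmp_path / run / "report.html")
            render(doc, "md", tmp_path / run / "report.md")
        for name in ("report.html", "report.md", "report_files/AGE_hist.png"):
            assert (tmp_path / "r1" / name).read_bytes() == (tmp_path / "r2" / name).read_bytes()

    def test_unknown_format_rejected(self, clean_pair, tmp_path):
        from phenocheck import PhenocheckError

        doc = create_awareness_report(*clean_pair, timestamp=TS)
        with pytest.raises(PhenocheckError, match="format"):
            render(doc, "pdf", tmp_path / "x.pdf")


class TestRobustnessOnDirtyData:
    @pytest.mark.parametrize("kind", sorted(ERROR_KINDS))
    def test_reports_never_crash_on_injected_errors(self, clean_pair, kind, tmp_path):
        ds, dd, _ = inject_error(*clean_pair, kind, seed=5)
        doc = create_report(ds, dd, timestamp=TS, with_figures=False)
        assert doc.sections
        aw = create_awareness_report(ds, dd, timestamp=TS)
        render(aw, "md", tmp_path / f"{kind}.md")
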