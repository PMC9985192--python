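"""Unit tests for the check panel, plus the brute-force range-check oracle."""

import numpy as np
import pytest

from phenocheck import (
    DataDictionary,
    MissingCodeSpec,
    PhenotypeDataset,
    VariableDefinition,
    check_report,
)
from phenocheck.checks import (
    PANEL_ORDER,
    CheckConfig,
    description_check,
    dimension_check,
    field_check,
    id_check,
    minmax_check,
    missing_value_check,
    na_check,
    name_check,
    normalize_code,
    pkg_field_check,
    row_check,
    type_check,
    values_check,
)

ALL_FIELDS = ["VARNAME", "VARDESC", "UNITS", "TYPE", "MIN", "MAX", "VALUES"]


def make_pair(columns, variables, present_fields=None, id_name="SUBJECT_ID"):
    """Small inline fixture: columns is {name: [raw, ...]} without the ID."""
    n = len(next(iter(columns.values())))
    cols = {id_name: [f"S{i}" for i in range(n)]}
    cols.update(columns)
    ds = PhenotypeDataset.from_raw(id_name, cols)
    dd = DataDictionary(
        variables=variables, present_fields=list(present_fields or ALL_FIELDS)
    )
    return ds, dd


def var(name, desc="d", **kw):
    kw.setdefault("type", "integer")
    return VariableDefinition(name=name, description=desc, **kw)


class TestNormalizeCode:
    @pytest.mark.parametrize(
        "a, b",
        [("-9999", "-9999.0"), ("-9999", " -9999 "), ("1e3", "1000"), ("0", "0.0")],
    )
    def test_numeric_equivalence(self, a, b):
        assert normalize_code(a) == normalize_code(b)

    def test_text_codes_compare_exactly(self):
        assert normalize_code("NA") == "NA"
        assert normalize_code("NA") != normalize_code("na")


class TestFieldChecks:
    def test_required_fields(self):
        dd = DataDictionary(present_fields=ALL_FIELDS)
        assert field_check(dd).status == "pass"
        dd = DataDictionary(present_fields=[f for f in ALL_FIELDS if f != "UNITS"])
        res = field_check(dd)
        assert res.status == "fail"
        assert [f.value for f in res.details] == ["UNITS"]

    def test_empty_header_lists_all_required(self):
        res = field_check(DataDictionary(present_fields=[]))
        assert [f.value for f in res.details] == ["VARNAME", "VARDESC", "UNITS", "VALUES"]

    def test_pkg_fields_and_remediation_hint(self):
        dd = DataDictionary(present_fields=["VARNAME", "VARDESC", "UNITS", "VALUES"])
        res = pkg_field_check(dd)
        assert res.status == "fail"
        assert [f.value for f in res.details] == ["TYPE", "MIN", "MAX"]
        assert "add_missing_fields" in res.message
        res = pkg_field_check(DataDictionary(present_fields=ALL_FIELDS[:5] + ["VALUES"]))
        assert [f.value for f in res.details] == ["MAX"]


class TestDimensionAndNames:
    def test_counts(self):
        ds, dd = make_pair({"A": ["1"], "B": ["2"]}, [var("A"), var("B")])
        assert dimension_check(ds, dd).status == "pass"
        ds2, dd2 = make_pair({"A": ["1"], "B": ["2"]}, [var("A")])
        res = dimension_check(ds2, dd2)
        assert res.status == "fail" and "2" in res.details[0].value

    def test_id_dialect_dictionary_defines_id(self):
        # when the dictionary has a row for the ID column, it is counted
        ds, dd = make_pair(
            {"A": ["1"]}, [var("SUBJECT_ID", type="string"), var("A")]
        )
        assert dimension_check(ds, dd).status == "pass"
        assert name_check(ds, dd).status == "pass"

    def test_name_sets_and_order(self):
        ds, dd = make_pair({"A": ["1"], "B": ["2"]}, [var("B"), var("A")])
        res = name_check(ds, dd)
        assert res.status == "fail"
        assert "reorder_dictionary" in res.details[0].note
        ds2, dd2 = make_pair({"BMI": ["1"]}, [var("OTHER")])
        notes = {f.variable: f.note for f in name_check(ds2, dd2).details}
        assert "not in dictionary" in notes["BMI"]
        assert "not in data set" in notes["OTHER"]


class TestIdAndRows:
    def test_id_rename_missing_duplicate(self):
        ds = PhenotypeDataset.from_raw("ID", {"ID": ["S1", "S1", ""], "X": ["1", "2", "3"]})
        res = id_check(ds, "SUBJECT_ID")
        notes = " ".join(f.note for f in res.details)
        assert "rename" in notes and "duplicated" in notes and "missing" in notes
        ok = PhenotypeDataset.from_raw("SUBJECT_ID", {"SUBJECT_ID": ["S1", "S2"], "X": ["1", "2"]})
        assert id_check(ok, "SUBJECT_ID").status == "pass"

    def test_duplicate_and_empty_rows(self):
        ds = PhenotypeDataset.from_raw(
            "SUBJECT_ID",
            {"SUBJECT_ID": ["S1", "S2", "S3"], "X": ["1", "1", ""], "Y": ["a", "a", ""]},
        )
        res = row_check(ds)
        assert res.status == "fail"
        notes = " ".join(f.note for f in res.details)
        assert "[1, 2]" in notes  # duplicated phenotype data
        assert any(f.row == 3 for f in res.details)  # empty row


class TestNaCheck:
    def make(self, x_cells):
        # second variable keeps rows non-empty: fully empty rows are
        # row_check territory and excluded from na_check by design
        ds, dd = make_pair(
            {"X": x_cells, "Y": ["9"] * len(x_cells)},
            [var("X", value_cells=["-9999=missing value"]), var("Y")],
        )
        return ds, dd

    def test_mixed_encoding_informational_by_default(self):
        ds, dd = self.make(["1", "", "-9999"])
        res = na_check(ds, dd)
        assert res.status == "pass"
        assert any("inconsistent" in f.note for f in res.info)

    def test_mixed_encoding_fails_when_escalated(self):
        ds, dd = self.make(["1", "", "-9999"])
        assert na_check(ds, dd, severity="fail").status == "fail"

    def test_native_missing_count_reported(self):
        ds, dd = self.make(["1", "", ""])
        res = na_check(ds, dd)
        assert res.status == "pass"
        assert any(f.value == "2" for f in res.info)

    def test_fully_empty_rows_belong_to_row_check(self):
        # a row with no phenotype data must not create a mixed-encoding failure
        ds, dd = make_pair(
            {"X": ["-9999", ""], "Y": ["1", ""]},
            [var("X", value_cells=["-9999=missing value"]), var("Y")],
        )
        assert na_check(ds, dd, severity="fail").status == "pass"


class TestDescriptions:
    def test_duplicates_and_empties(self):
        dd = DataDictionary(
            variables=[
                var("A", "Body mass index"),
                var("B", "body  MASS index"),  # case/whitespace-insensitive duplicate
                var("C", ""),
            ],
            present_fields=ALL_FIELDS,
        )
        res = description_check(dd)
        notes = " ".join(f.note for f in res.details)
        assert "'body mass index'" in notes
        assert any(f.variable == "C" and "empty" in f.note for f in res.details)

    def test_duplicate_names(self):
        dd = DataDictionary(variables=[var("A"), var("A")], present_fields=ALL_FIELDS)
        assert any("VARNAME" in f.note for f in description_check(dd).details)


class TestTypeCheck:
    def test_integer_and_decimal(self):
        ds, dd = make_pair(
            {"I": ["1", "3.5", "2"], "D": ["1", "2.5", "-9999"]},
            [var("I", type="integer"),
             var("D", type="decimal", value_cells=["-9999=missing value"])],
        )
        res = type_check(ds, dd)
        assert res.status == "fail"
        assert [(f.variable, f.row, f.value) for f in res.details] == [("I", 2, "3.5")]

    def test_unrecognized_and_empty_labels_are_informational(self):
        ds, dd = make_pair(
            {"A": ["x"], "B": ["y"]},
            [var("A", type="widget"), var("B", type="")],
        )
        res = type_check(ds, dd)
        assert res.status == "pass" and len(res.info) == 2

    def test_encoded_expects_integer_codes(self):
        ds, dd = make_pair(
            {"E": ["0", "1.5"]},
            [var("E", type="encoded value", value_cells=["0=no", "1=yes"])],
        )
        assert type_check(ds, dd).details[0].value == "1.5"


class TestValuesCheck:
    def test_complete_map_passes(self):
        ds, dd = make_pair(
            {"E": ["0", "1", "-9999"]},
            [var("E", type="encoded value",
                 value_cells=["0=no", "1=yes", "-9999=missing value"])],
        )
        assert values_check(ds, dd).status == "pass"

    def test_observed_value_missing_from_map(self):
        ds, dd = make_pair(
            {"E": ["0", "2"]},
            [var("E", type="encoded value", value_cells=["0=no", "1=yes"])],
        )
        res = values_check(ds, dd)
        assert res.status == "fail"
        assert res.details[0].value == "2"
        # unobserved map code is informational only
        assert any(f.value == "1" for f in res.info)

    def test_malformed_entry_fails(self):
        ds, dd = make_pair(
            {"E": ["0"]},
            [var("E", type="encoded value", value_cells=["0=no", "nope"])],
        )
        res = values_check(ds, dd)
        assert res.status == "fail" and res.details[0].value == "nope"


class TestMissingValueCheck:
    def test_observed_code_needs_entry(self):
        ds, dd = make_pair(
            {"X": ["1", "-4444"], "Y": ["1", "-9999"]},
            [var("X"), var("Y", value_cells=["-9999=missing value"])],
        )
        res = missing_value_check(ds, dd)
        assert [(f.variable, f.value) for f in res.details] == [("X", "-4444")]

    def test_no_codes_observed_passes(self):
        ds, dd = make_pair({"X": ["1", "2"]}, [var("X")])
        assert missing_value_check(ds, dd).status == "pass"

    def test_harvested_code_from_meaning_pattern(self):
        # -7777 is neither global nor per-variable, but its meaning says missing
        ds, dd = make_pair(
            {"X": ["1", "-7777"]},
            [var("X", value_cells=["-7777=Missing: refused"])],
        )
        codes = MissingCodeSpec()
        eff = codes.effective_codes("X", dd.variables[0])
        assert normalize_code("-7777") in eff
        assert missing_value_check(ds, dd, codes).status == "pass"


class TestMinMaxCheck:
    def test_inclusive_bounds(self):
        ds, dd = make_pair(
            {"X": ["0", "3", "10"]}, [var("X", min="0", max="10")]
        )
        assert minmax_check(ds, dd).status == "pass"

    def test_violations_and_code_exclusion(self):
        ds, dd = make_pair(
            {"X": ["11", "-1", "-9999"]},
            [var("X", min="0", max="10", value_cells=["-9999=missing value"])],
        )
        res = minmax_check(ds, dd)
        assert [(f.value, "MAX" in f.note) for f in res.details] == [
            ("11", True),
            ("-1", False),
        ]

    def test_unparseable_bound(self):
        ds, dd = make_pair({"X": ["1"]}, [var("X", min="low", max="10")])
        res = minmax_check(ds, dd)
        assert res.status == "fail" and "unparseable" in res.details[0].note

    def test_skips_empty_bounds(self):
        ds, dd = make_pair({"X": ["999"]}, [var("X")])
        assert minmax_check(ds, dd).status == "pass"

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_brute_force_oracle(self, seed):
        res_details, oracle = _minmax_vs_oracle(seed, n_vars=50)
        assert res_details == oracle


def _minmax_vs_oracle(seed, n_vars):
    """Random single-variable fixtures: minmax_check vs filter-then-scan."""
    rng = np.random.default_rng(seed)
    codes = MissingCodeSpec()
    got, expected = [], []
    for v_idx in range(n_vars):
        lo = int(rng.integers(-10, 10))
        hi = lo + int(rng.integers(0, 30))
        cells = []
        for _ in range(int(rng.integers(1, 40))):
            r = rng.random()
            if r < 0.1:
                cells.append("")
            elif r < 0.2:
                cells.append("-9999")
            elif r < 0.3:
                cells.append(str(int(rng.integers(lo - 20, hi + 21))))
            else:
                cells.append(str(int(rng.integers(lo, hi + 1))))
        name = f"V{v_idx}"
        ds, dd = make_pair(
            {name: cells},
            [var(name, min=str(lo), max=str(hi),
                 value_cells=["-9999=missing value"])],
        )
        res = minmax_check(ds, dd, codes)
        got += [(f.variable, f.row, f.value) for f in res.details]
        # independent brute force: drop empties and codes, scan against bounds
        for i, raw in enumerate(cells, start=1):
            if raw == "" or raw == "-9999":
                continue
            if not (lo <= int(raw) <= hi):
                expected.append((name, i, raw))
    return got, expected


class TestPanelOrchestration:
    def test_canonical_order_and_overall(self, clean_pair):
        report = check_report(*clean_pair)
        assert [r.check_name for r in report.results] == list(PANEL_ORDER)
        assert report.overall and report.failed == []

    def test_prerequisite_gating(self, clean_pair):
        ds, dd = clean_pair
        stripped = DataDictionary(
            variables=dd.variables,
            present_fields=[f for f in dd.present_fields if f not in ("TYPE", "MIN", "MAX")],
        )
        report = check_report(ds, stripped)
        assert report.result("pkg_field_check").status == "fail"
        assert report.result("type_check").status == "not_run"
        assert report.result("minmax_check").status == "not_run"
        assert "pkg_field_check" in report.result("type_check").message
        assert not report.overall

    def test_idempotence(self, clean_pair):
        assert check_report(*clean_pair) == check_report(*clean_pair)

    def test_pass_iff_details_empty(self, clean_pair):
        for r in check_report(*clean_pair).results:
            assert (r.status == "pass") == (len(r.details) == 0)

    def test_disabled_checks_are_omitted(self, clean_pair):
        cfg = CheckConfig(disabled_checks={"row_check"})
        names = [r.check_name for r in check_report(*clean_pair, config=cfg).results]
        assert "row_check" not in names and len(names) == len(PANEL_ORDER) - 1
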