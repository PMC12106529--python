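"""Cohort table fixture, CSV round-trip, and consistency checks."""

import math

import pytest

from mesothresh import (
    CohortRecord,
    CohortTable,
    DataSchemaError,
    DataValidationError,
    builtin_table1,
    load_cohorts,
    save_cohorts,
    validate_consistency,
)
from mesothresh.cohorts import CSV_COLUMNS


class TestBuiltinTable:
    @pytest.mark.parametrize("name, field, expected", [
        ("Québec", "cumulative_fcc_years", 600.0),
        ("Québec", "meso_cases", 33),
        ("Québec", "expected_mortality", 5913.0),
        ("Québec", "excess_rate", 0.0054),
        ("Québec", "survival", 0.995),
        ("Russian", "intensity_fcc", 2.24),
        ("Russian", "duration_years", 15.0),
        ("Russian", "cumulative_fcc_years", 33.6),
        ("Russian", "meso_cases", 13),
        ("Russian", "expected_mortality", 10351.0),
        ("Balangero", "excess_rate", 0.0128),
        ("Connecticut", "excess_rate", 0.00072),
    ])
    def test_published_cells(self, table1, name, field, expected):
        assert getattr(table1[name], field) == expected

    def test_six_cohorts(self, table1):
        assert len(table1) == 6

    def test_column_totals(self, table1):
        assert sum(table1.column("meso_cases")) == 55
        assert sum(table1.column("expected_mortality")) == 17_953

    def test_ce_close_to_intensity_times_duration(self, table1):
        for r in table1:
            assert math.isclose(
                r.intensity_fcc * r.duration_years,
                r.cumulative_fcc_years,
                rel_tol=0.02,
            )

    def test_survival_complements_excess(self, table1):
        for r in table1:
            assert abs(r.survival + r.excess_rate - 1.0) <= 0.001

    def test_cases_bounded_by_expected_mortality(self, table1):
        for r in table1:
            assert r.meso_cases <= r.expected_mortality


class TestCsvRoundTrip:
    def test_round_trip_identity(self, table1, tmp_path):
        path = tmp_path / "cohorts.csv"
        save_cohorts(table1, path)
        assert load_cohorts(path) == table1

    def test_round_trip_synthetic_many_digits(self, tmp_path):
        rec = CohortRecord("x", 12.345678901234, 3.14159265358979, 38.7850941358,
                           25.0, 3, 812.5, 0.00369230769231, 0.99630769230769)
        path = tmp_path / "one.csv"
        save_cohorts(CohortTable([rec]), path)
        back = load_cohorts(path)[0]
        for field in CSV_COLUMNS[1:]:
            a, b = getattr(rec, field), getattr(back, field)
            assert math.isclose(a, b, rel_tol=1e-12, abs_tol=1e-15)

    def test_empty_file_is_schema_error(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("")
        with pytest.raises(DataSchemaError):
            load_cohorts(path)

    def test_missing_column_named_in_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("name,duration_years\nx,1\n")
        with pytest.raises(DataSchemaError, match="intensity_fcc"):
            load_cohorts(path)

    def test_non_numeric_cell_reports_row(self, table1, tmp_path):
        path = tmp_path / "cohorts.csv"
        save_cohorts(table1, path)
        text = path.read_text().replace("721", "seven21")
        path.write_text(text)
        with pytest.raises(DataValidationError, match="row 1"):
            load_cohorts(path)

    def test_negative_expected_mortality_rejected(self, table1, tmp_path):
        path = tmp_path / "cohorts.csv"
        save_cohorts(table1, path)
        path.write_text(path.read_text().replace("5913", "-5913"))
        with pytest.raises(DataValidationError):
            load_cohorts(path)


class TestRecordInvariants:
    def test_duplicate_names_rejected(self, table1):
        with pytest.raises(DataValidationError):
            CohortTable([table1[0], table1[0]])

    def test_empty_table_rejected(self):
        with pytest.raises(DataValidationError):
            CohortTable([])

    @pytest.mark.parametrize("kwargs", [
        dict(duration_years=0.0),
        dict(onset_age=-1.0),
        dict(excess_rate=1.5),
        dict(meso_cases=-1),
        dict(meso_cases=600),  # exceeds expected mortality
    ])
    def test_invalid_fields_rejected(self, kwargs):
        base = dict(name="x", duration_years=10.0, intensity_fcc=1.0,
                    cumulative_fcc_years=10.0, onset_age=25.0, meso_cases=1,
                    expected_mortality=100.0, excess_rate=0.01, survival=0.99)
        with pytest.raises(DataValidationError):
            CohortRecord(**{**base, **kwargs})


class TestConsistencyChecks:
    def test_connecticut_case_rate_flagged(self, table1):
        # 2/274 = 0.0073 disagrees with the published excess of 0.00072
        findings = validate_consistency(table1, tol_rate=0.10)
        flagged = {f.cohort for f in findings if f.check == "cases_vs_excess"}
        assert "Connecticut" in flagged

    def test_no_cumulative_exposure_findings(self, table1):
        findings = validate_consistency(table1, tol_ce=0.02)
        assert not [f for f in findings if f.check == "ce_vs_product"]

    def test_clean_record_has_no_findings(self):
        rec = CohortRecord("clean", 10.0, 2.0, 20.0, 25.0, 0, 100.0, 0.0, 1.0)
        assert validate_consistency(CohortTable([rec])) == []

    def test_findings_never_raise(self, table1):
        # tight tolerances produce findings, not exceptions
        findings = validate_consistency(table1, tol_ce=0.001, tol_rate=0.0001)
        assert isinstance(findings, list) and findings

    def test_bad_tolerances_rejected(self, table1):
        with pytest.raises(ValueError):
            validate_consistency(table1, tol_ce=0.0)
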