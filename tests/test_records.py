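"""Reading, validation, classification and filtering of capture records."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from manateebci import (
    MorphRecord,
    assign_age_class,
    filter_analysis_set,
    measurement_subsets,
    merge_field_scores,
    read_records,
    write_records,
)
from manateebci.records import SchemaError


class TestReadRecords:
    def test_reads_valid_rows_with_optional_weight(self, small_csv):
        result = read_records(small_csv)
        assert len(result.records) == 3
        assert result.rejected == []
        assert result.records[1].w_kg is None
        assert result.records[0].sl_m == pytest.approx(2.60)

    def test_cm_units_converted_to_meters(self, tmp_path):
        path = tmp_path / "cm.csv"
        path.write_text(
            "id,country,location,habitat,sex,sl,ug,w,field_score,pregnant_late,date\n"
            "B1,Cuba,Cuba,coastal,M,260,190,330.1,C3,false,\n")
        rec = read_records(path, units="cm_kg").records[0]
        assert rec.sl_m == pytest.approx(2.60)
        assert rec.ug_m == pytest.approx(1.90)
        assert rec.w_kg == pytest.approx(330.1)  # mass unchanged

    def test_negative_length_is_row_failure_not_exception(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "id,country,location,habitat,sex,sl,ug,w,field_score,pregnant_late,date\n"
            "C1,Cuba,Cuba,coastal,M,-1,1.9,330,C3,false,\n"
            "C2,Cuba,Cuba,coastal,F,2.2,1.6,250,C3,false,\n")
        result = read_records(path)
        assert len(result.records) == 1
        assert len(result.rejected) == 1
        assert result.rejected[0].reason == "invalid_measurement"

    def test_non_numeric_measurement_is_row_failure(self, tmp_path):
        path = tmp_path / "nn.csv"
        path.write_text(
            "id,country,location,habitat,sex,sl,ug,w,field_score,pregnant_late,date\n"
            "D1,Cuba,Cuba,coastal,M,abc,1.9,330,C3,false,\n")
        result = read_records(path)
        assert result.records == []
        assert "non_numeric:sl" in result.rejected[0].detail

    def test_unknown_column_raises_schema_error_naming_it(self, tmp_path):
        path = tmp_path / "extra.csv"
        path.write_text("id,country,location,habitat,sex,sl,ug,w,"
                        "field_score,pregnant_late,date,flipper\nX,,,,,,,,,,,\n")
        with pytest.raises(SchemaError, match="flipper"):
            read_records(path)

    def test_missing_file_raises_io_error(self, tmp_path):
        with pytest.raises(OSError):
            read_records(tmp_path / "nope.csv")

    def test_unit_round_trip_preserves_full_precision(self, tmp_path):
        path = tmp_path / "cm2.csv"
        path.write_text(
            "id,country,location,habitat,sex,sl,ug,w,field_score,pregnant_late,date\n"
            "E1,Cuba,Cuba,coastal,M,233.7,171.3,301.25,C3,false,\n")
        recs = read_records(path, units="cm_kg").records
        out = tmp_path / "m.csv"
        write_records(recs, out)
        again = read_records(out, units="m_kg").records
        assert again[0].sl_m == recs[0].sl_m
        assert again[0].ug_m == recs[0].ug_m
        assert again[0].w_kg == recs[0].w_kg


class TestAgeClass:
    @pytest.mark.parametrize("sl,expected", [
        (1.60, "calf"),
        (2.00, "subadult"),
        (2.60, "adult"),
        (1.75, "subadult"),  # both printed boundaries belong to subadult
        (2.25, "subadult"),
        (1.7499999, "calf"),
        (2.2500001, "adult"),
    ])
    def test_boundaries(self, sl, expected):
        assert assign_age_class(sl) == expected

    def test_missing_length_gives_sentinel_not_calf(self):
        assert assign_age_class(None) is None

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError):
            assign_age_class(0.0)


class TestFieldScores:
    @pytest.mark.parametrize("score,expected", [
        ("C1", "thin"), ("C2", "thin"), ("C3", "ideal"),
        ("C4", "obese"), ("C5", "obese"), ("unscored", "unscored"),
    ])
    def test_merge(self, score, expected):
        assert merge_field_scores(score) == expected

    def test_unknown_label_is_schema_error(self):
        with pytest.raises(SchemaError):
            merge_field_scores("C9")


class TestFilterAnalysisSet:
    def _records(self, make_record):
        return [
            make_record(id="R1", field_score="C3"),
            make_record(id="R2", field_score="C3"),
            make_record(id="R3", field_score="C1"),
            make_record(id="R4", field_score="C4"),
            make_record(id="R5", field_score="unscored"),
        ]

    def test_default_keeps_ideal_and_unscored(self, make_record):
        retained, report = filter_analysis_set(self._records(make_record))
        assert [r.id for r in retained] == ["R1", "R2", "R5"]
        assert report.n_excluded_by_reason == {"thin_score": 1, "obese_score": 1}
        assert report.balanced

    def test_condition_group_mode_reincorporates_thin_and_obese(self, make_record):
        retained, report = filter_analysis_set(
            self._records(make_record), include_condition_groups=True)
        assert len(retained) == 5
        assert report.balanced

    def test_late_pregnancy_always_excluded(self, make_record):
        recs = [make_record(id="P1", field_score="C3", pregnant_late=True)]
        for flag in (False, True):
            retained, report = filter_analysis_set(
                recs, include_condition_groups=flag)
            assert retained == []
            assert report.n_excluded_by_reason == {"late_pregnancy": 1}

    def test_listed_exclusions_reported(self, make_record):
        retained, report = filter_analysis_set(
            self._records(make_record), exclude_ids=["R1"])
        assert "R1" not in [r.id for r in retained]
        assert report.n_excluded_by_reason["listed_exclusion"] == 1

    @given(st.lists(st.tuples(
        st.sampled_from(["C1", "C2", "C3", "C4", "C5", "unscored"]),
        st.booleans()), max_size=40))
    @settings(max_examples=50, deadline=None)
    def test_partition_property(self, rows):
        recs = [MorphRecord(id=f"H{i}", habitat="coastal", field_score=s,
                            pregnant_late=p, sl_m=2.0)
                for i, (s, p) in enumerate(rows)]
        retained, report = filter_analysis_set(recs)
        assert report.balanced
        assert report.n_input == len(recs)
        assert report.n_retained == len(retained)


class TestMeasurementSubsets:
    def test_membership_by_availability(self, make_record):
        full = make_record(id="S1")
        no_w = make_record(id="S2", w_kg=None)
        only_w = make_record(id="S3", sl_m=None, ug_m=None)
        subsets = measurement_subsets([full, no_w, only_w])
        assert [r.id for r in subsets["bci1"]] == ["S1", "S2"]
        assert [r.id for r in subsets["bci2"]] == ["S1"]
        assert [r.id for r in subsets["bci3"]] == ["S1"]
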