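import datetime as dt

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dectresp.cohort import (
    CA125Sample,
    ClassificationResult,
    LesionMeasurement,
    PatientCourse,
    ResponseCategory,
    eligibility_filter,
    read_cohort,
    write_cohort,
)
from dectresp.errors import IntegrityError, RowError, SchemaError
from dectresp.simulate import SimulationConfig, simulate_cohort

from conftest import day, make_course


class TestDomainTypes:
    def test_negative_diameter_rejected(self):
        with pytest.raises(ValueError):
            LesionMeasurement(
                lesion_id="L1", timepoint_date=day(0), longest_diameter_mm=-3
            )

    def test_zero_diameter_is_disappearance(self):
        m = LesionMeasurement(
            lesion_id="L1", timepoint_date=day(0), longest_diameter_mm=0
        )
        assert m.longest_diameter_mm == 0

    def test_nonpositive_ca125_rejected(self):
        with pytest.raises(ValueError):
            CA125Sample(sample_date=day(0), value_u_per_ml=0)

    def test_duplicate_ca125_dates_rejected(self):
        with pytest.raises(ValueError, match="duplicate CA125"):
            make_course(ca125_specs=None).model_copy()
            PatientCourse(
                patient_id="P1",
                ca125=[
                    CA125Sample(sample_date=day(0), value_u_per_ml=10),
                    CA125Sample(sample_date=day(0), value_u_per_ml=20),
                ],
                last_followup_date=day(10),
            )

    def test_measurement_after_death_rejected(self):
        with pytest.raises(ValueError, match="horizon"):
            make_course(
                lesion_specs={"L1": {100: (10,)}}, death_day=50, last_followup_day=50
            )

    def test_ca125_sorted_after_ingestion(self):
        c = make_course(ca125_specs={61: 50.0, 0: 100.0, 30: 70.0})
        assert [s.sample_date for s in c.ca125] == [day(0), day(30), day(61)]

    def test_overlapping_lines_rejected(self):
        with pytest.raises(ValueError, match="overlapping"):
            make_course(line_days=((0, 100), (50, 200)))

    def test_classification_responder_defaults(self):
        r = ClassificationResult(
            patient_id="P1",
            criterion="RECIST",
            category=ResponseCategory.SD,
            assessment_date=day(91),
        )
        assert r.responder is True
        pd = r.model_copy(update={"category": ResponseCategory.PD, "responder": None})
        assert ClassificationResult.model_validate(pd.model_dump()).responder is False

    def test_ne_has_no_responder_flag(self):
        r = ClassificationResult(
            patient_id="P1",
            criterion="DECT",
            category=ResponseCategory.NE,
            assessment_date=day(0),
        )
        assert r.responder is None
        with pytest.raises(ValueError):
            ClassificationResult(
                patient_id="P1",
                criterion="DECT",
                category=ResponseCategory.NE,
                responder=True,
                assessment_date=day(0),
            )


class TestIO:
    def test_roundtrip_two_patients(self, tmp_path):
        cohort = [make_course(patient_id="A"), make_course(patient_id="B")]
        write_cohort(cohort, tmp_path / "bundle")
        back = read_cohort(tmp_path / "bundle")
        assert back == cohort

    def test_roundtrip_json(self, tmp_path):
        cohort, _ = simulate_cohort(SimulationConfig(n_patients=5, seed=4))
        write_cohort(cohort, tmp_path / "c.json", format="json")
        assert read_cohort(tmp_path / "c.json", format="json") == cohort

    def test_empty_cohort_headers_only(self, tmp_path):
        paths = write_cohort([], tmp_path / "empty")
        assert len(paths) == 4
        for p in paths:
            lines = p.read_text().strip().splitlines()
            assert len(lines) == 1  # header only
        assert read_cohort(tmp_path / "empty") == []

    def test_optional_fields_roundtrip_absence(self, tmp_path):
        course = make_course(lesion_specs={"L1": {0: (10, None, None)}})
        assert course.death_date is None
        write_cohort([course], tmp_path / "b")
        (back,) = read_cohort(tmp_path / "b")
        assert back.death_date is None
        assert back.lesions[0].iodine_mg_per_ml is None
        assert back == course

    def test_simulated_cohort_roundtrip(self, tmp_path):
        cohort, _ = simulate_cohort(SimulationConfig(n_patients=12, seed=9))
        write_cohort(cohort, tmp_path / "b")
        assert read_cohort(tmp_path / "b") == cohort

    @settings(max_examples=15, deadline=None)
    @given(seed=st.integers(0, 10**6))
    def test_roundtrip_property_random_cohorts(self, tmp_path_factory, seed):
        cohort, _ = simulate_cohort(SimulationConfig(n_patients=3, seed=seed))
        out = tmp_path_factory.mktemp("rt")
        write_cohort(cohort, out / "b")
        assert read_cohort(out / "b") == cohort

    def test_missing_column_schema_error(self, tmp_path):
        write_cohort([make_course()], tmp_path / "b")
        lesions = tmp_path / "b" / "lesions.csv"
        text = lesions.read_text().replace("longest_diameter_mm", "diameter")
        lesions.write_text(text)
        with pytest.raises(SchemaError, match="longest_diameter_mm"):
            read_cohort(tmp_path / "b")

    def test_negative_diameter_row_error_with_line(self, tmp_path):
        write_cohort([make_course(lesion_specs={"L1": {0: (10,)}})], tmp_path / "b")
        lesions = tmp_path / "b" / "lesions.csv"
        with open(lesions, "a") as fh:
            fh.write("P1,L2,2020-01-01,-3,,,\n")
        with pytest.raises(RowError, match="line 3"):
            read_cohort(tmp_path / "b")

    def test_unparseable_date_row_error(self, tmp_path):
        write_cohort([make_course(ca125_specs={0: 100.0})], tmp_path / "b")
        ca = tmp_path / "b" / "ca125.csv"
        with open(ca, "a") as fh:
            fh.write("P1,not-a-date,50\n")
        with pytest.raises(RowError, match="unparseable date"):
            read_cohort(tmp_path / "b")

    def test_duplicate_lesion_key_integrity_error(self, tmp_path):
        write_cohort([make_course(lesion_specs={"L1": {0: (10,)}})], tmp_path / "b")
        lesions = tmp_path / "b" / "lesions.csv"
        with open(lesions, "a") as fh:
            fh.write("P1,L1,2020-01-01,12,,,\n")
        with pytest.raises(IntegrityError):
            read_cohort(tmp_path / "b")

    def test_cm_units_converted(self, tmp_path):
        write_cohort([make_course(lesion_specs={"L1": {0: (2.98,)}})], tmp_path / "b")
        (back,) = read_cohort(tmp_path / "b", diameter_units="cm")
        assert back.lesions[0].longest_diameter_mm == pytest.approx(29.8)


class TestEligibility:
    def test_single_iodine_timepoint_not_evaluable(self):
        course = make_course(lesion_specs={"L1": {0: (10, 1.2, 7.0), 91: (9,)}})
        assert not course.dect_evaluable
        evaluable, report = eligibility_filter([course])
        assert evaluable == []
        assert report.counts == {"single iodine imaging timepoint": 1}

    def test_62_patients_22_single_scan(self):
        cohort = []
        for i in range(62):
            single = i < 22
            specs = {
                "L1": {
                    0: (10, 1.2, 7.0),
                    91: (9, None, None) if single else (9, 1.0, 7.0),
                }
            }
            cohort.append(make_course(patient_id=f"P{i}", lesion_specs=specs))
        evaluable, report = eligibility_filter(cohort)
        assert len(evaluable) == 40
        assert report.n_excluded == 22

    def test_all_evaluable_identity(self):
        cohort = [
            make_course(
                patient_id=f"P{i}",
                lesion_specs={"L1": {0: (10, 1.2, 7.0), 91: (9, 1.0, 7.0)}},
            )
            for i in range(3)
        ]
        evaluable, report = eligibility_filter(cohort)
        assert evaluable == cohort
        assert report.n_excluded == 0

    def test_empty(self):
        evaluable, report = eligibility_filter([])
        assert evaluable == [] and report.counts == {}

    @settings(max_examples=10, deadline=None)
    @given(seed=st.integers(0, 10**6), k=st.integers(0, 6))
    def test_idempotent_and_partition(self, seed, k):
        cohort, _ = simulate_cohort(
            SimulationConfig(n_patients=6, n_single_scan=k, seed=seed)
        )
        once, report = eligibility_filter(cohort)
        twice, report2 = eligibility_filter(once)
        assert twice == once and report2.n_excluded == 0
        assert len(once) + report.n_excluded == len(cohort)
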