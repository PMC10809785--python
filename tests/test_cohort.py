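import json

import numpy as np
import pytest

from pydantic import ValidationError

from survplan import cohort_profile, generate_cohort, load_preset, validate_patient
from survplan.cohort import CohortPreset
from survplan.model import to_json

from conftest import make_patient, rt_course


@pytest.fixture(scope="module")
def table1():
    return load_preset("table1")


class TestPreset:
    def test_table1_disease_probs_normalized(self, table1):
        assert abs(sum(table1.disease_probs.values()) - 1.0) < 1e-9
        assert table1.disease_probs["leukemia"] == pytest.approx(724 / 2558)

    def test_inconsistent_joint_probability_rejected(self, table1):
        raw = table1.model_dump()
        raw["p_rt_and_medical"] = 0.5  # > p_radiotherapy
        with pytest.raises(ValidationError, match="p_rt_and_medical"):
            CohortPreset.model_validate(raw)

    def test_age_mean_outside_range_rejected(self, table1):
        raw = table1.model_dump()
        raw["age_mean"] = 30.0
        with pytest.raises(ValidationError, match="age_mean"):
            CohortPreset.model_validate(raw)

    def test_load_from_yaml_path(self, table1, tmp_path):
        import yaml

        path = tmp_path / "preset.yaml"
        path.write_text(yaml.safe_dump(table1.model_dump()))
        assert load_preset(path).p_tumor_bank == table1.p_tumor_bank


class TestGenerateCohort:
    def test_n_zero_empty(self):
        assert generate_cohort("table1", n=0) == []

    def test_same_seed_identical_byte_for_byte(self):
        a = generate_cohort("table1", n=25, seed=42)
        b = generate_cohort("table1", n=25, seed=42)
        assert [to_json(p) for p in a] == [to_json(p) for p in b]

    def test_different_seeds_differ(self):
        a = generate_cohort("table1", n=25, seed=1)
        b = generate_cohort("table1", n=25, seed=2)
        assert [to_json(p) for p in a] != [to_json(p) for p in b]

    def test_degenerate_all_monitoring_preset(self, table1):
        raw = table1.model_dump()
        raw.update(p_simple_monitoring=1.0, p_medical_treatment=0.0, p_surgery=0.0,
                   p_radiotherapy=0.0, p_rt_and_medical=0.0, p_autotransplant=0.0,
                   p_allograft=0.0)
        cohort = generate_cohort(CohortPreset.model_validate(raw), n=20, seed=3)
        for p in cohort:
            assert p.first_diagnosis.treatment_lines[0].is_simple_monitoring

    def test_all_records_revalidate(self):
        for p in generate_cohort("table1", n=50, seed=5):
            assert validate_patient(p.model_dump(mode="json")) == p

    def test_ages_within_published_range(self, table1):
        cohort = generate_cohort("table1", n=300, seed=9)
        lo, hi = table1.age_range
        for p in cohort:
            age = p.age_at(p.first_diagnosis.date)
            assert lo <= age <= hi + 0.01

    def test_engine_path_quotas_even_in_small_cohorts(self):
        cohort = generate_cohort("table1", n=10, seed=13)
        assert any(
            not rt.dosimetry_available
            for p in cohort for d in p.diagnoses
            for ln in d.treatment_lines for rt in ln.rt_courses
        )
        assert any(
            any(s.functional_impact == "complete_removal"
                for d in p.diagnoses for ln in d.treatment_lines for s in ln.surgeries)
            or any(e.event_type == "organ_loss" for e in p.follow_up_events)
            for p in cohort
        )
        assert any(p.predispositions for p in cohort)

    def test_exactly_one_research_refusal(self):
        cohort = generate_cohort("table1", n=200, seed=17)
        assert sum(1 for p in cohort if not p.consent_research) == 1

    def test_table_default_doses_match_packaged_table(self):
        from survplan import default_dose_table

        table = default_dose_table()
        for p in generate_cohort("table1", n=30, seed=19):
            for d in p.diagnoses:
                for ln in d.treatment_lines:
                    for course in ln.chemo_courses:
                        lookup = {e.agent: e.cumulative_dose
                                  for e in table.lookup(course.protocol_id, course.arm_id)}
                        for ad in course.agent_doses:
                            if ad.source == "table_default":
                                assert ad.cumulative_dose == lookup[ad.agent]


class TestCohortProfile:
    def test_hand_counted_profile(self):
        patients = [
            make_patient(patient_id="A", surgeries=[{
                "date": "2015-03-01", "organ": "kidney",
                "carcinological_impact": "complete_resection",
                "functional_impact": "none"}]),
            make_patient(patient_id="B", surgeries=[{
                "date": "2015-03-01", "organ": "brain",
                "carcinological_impact": "microscopically_incomplete",
                "functional_impact": "partial_removal"}]),
            make_patient(patient_id="C", rt_courses=[rt_course()]),
            make_patient(patient_id="D"),
        ]
        prof = cohort_profile(patients)
        assert prof.first_line_pct["surgery"] == 50.0
        assert prof.first_line_pct["radiotherapy"] == 25.0
        assert prof.first_line_pct["simple_monitoring"] == 25.0

    def test_empty_cohort_percentages_null(self):
        prof = cohort_profile([])
        assert prof.n == 0
        assert prof.mean_age is None
        assert prof.pct_male is None
        assert all(v is None for v in prof.first_line_pct.values())
        json.dumps(prof.to_dict())  # serializable

    def test_law_of_large_numbers_round_trip(self, table1):
        """At n=10^5 every profile percentage converges to its preset value
        within 3 binomial standard errors (the monitoring/'both' rates are
        the residuals implied by the joint construction, see docs)."""
        n = 100_000
        cohort = generate_cohort("table1", n=n, seed=1234)
        prof = cohort_profile(cohort)

        def se(p):
            return 100 * np.sqrt(p * (1 - p) / n)

        checks = {
            "surgery": (prof.first_line_pct["surgery"], table1.p_surgery),
            "medical": (prof.first_line_pct["medical_treatment"], table1.p_medical_treatment),
            "radiotherapy": (prof.first_line_pct["radiotherapy"], table1.p_radiotherapy),
            "tumor_bank": (prof.pct_tumor_bank, table1.p_tumor_bank),
            "male": (prof.pct_male, table1.sex_prob_male),
            "leukemia": (prof.disease_pct["leukemia"], table1.disease_probs["leukemia"]),
            "monitoring": (prof.first_line_pct["simple_monitoring"], table1.p_simple_monitoring),
            "recurrence": (prof.pct_recurrence, table1.p_recurrence),
            "second_cancer": (prof.pct_second_cancer, table1.p_second_cancer),
        }
        for name, (observed, target) in checks.items():
            assert abs(observed - 100 * target) <= 3 * se(target), (
                f"{name}: {observed:.2f} vs {100 * target:.2f}")

        ages = [p.age_at(p.first_diagnosis.date) for p in cohort]
        sem = np.std(ages) / np.sqrt(n)
        assert abs(np.mean(ages) - table1.age_mean) <= 3 * sem
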