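import datetime as dt

import pytest

from survplan import default_rulebase, validate_patient


@pytest.fixture(scope="session")
def rulebase():
    return default_rulebase()


def make_patient(
    *,
    patient_id="P001",
    sex="female",
    birth_date="2005-01-01",
    diagnosis_date="2015-01-15",
    disease="lymphoma",
    surgeries=(),
    chemo_courses=(),
    rt_courses=(),
    hsct=None,
    supportive_care=(),
    extra_lines=(),
    follow_up_events=(),
    predispositions=(),
    comorbidities=(),
    consent_research=True,
    residence_unit=None,
):
    """Build a small, valid patient record; every treatment list defaults to
    empty (simple monitoring)."""
    lines = [
        {
            "line_number": 1,
            "start_date": "2015-02-01",
            "end_date": "2015-11-01",
            "surgeries": list(surgeries),
            "chemo_courses": list(chemo_courses),
            "rt_courses": list(rt_courses),
            "hsct": hsct,
            "supportive_care": list(supportive_care),
        }
    ] + list(extra_lines)
    return validate_patient(
        {
            "patient_id": patient_id,
            "sex": sex,
            "birth_date": birth_date,
            "centers": ["C01"],
            "diagnoses": [
                {
                    "date": diagnosis_date,
                    "disease_category": disease,
                    "cancer_rank": 1,
                    "treatment_lines": lines,
                }
            ],
            "follow_up_events": list(follow_up_events),
            "predispositions": list(predispositions),
            "comorbidities": list(comorbidities),
            "consent_research": consent_research,
            "residence_unit": residence_unit,
        }
    )


def rt_course(
    fields=("supra_diaphragmatic",),
    prescribed=25.0,
    organ_doses=(),
    start="2015-05-01",
    end="2015-06-01",
):
    return {
        "start_date": start,
        "end_date": end,
        "fields_irradiated": list(fields),
        "prescribed_dose": prescribed,
        "dosimetry_available": bool(organ_doses),
        "organ_doses": [{"organ": o, "mean_dose": d} for o, d in organ_doses],
    }


def chemo_course(agent_doses, protocol="ALL-2020", arm="standard_risk",
                 start="2015-02-01", end="2015-08-01"):
    return {
        "protocol_id": protocol,
        "arm_id": arm,
        "start_date": start,
        "end_date": end,
        "agent_doses": [
            {"agent": a, "cumulative_dose": d, "source": "adapted"} for a, d in agent_doses
        ],
    }


AS_OF = dt.date(2024, 1, 1)
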