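"""Generate a personalized surveillance plan for one survivor.

A young woman treated for Hodgkin lymphoma with doxorubicin and cervical
radiotherapy (organ dosimetry available) gets a plan derived from the
packaged rule base: each item states the examination, how often it recurs,
and the strength of the underlying evidence.
"""

import datetime as dt

from survplan import default_rulebase, generate_plan, validate_patient

patient = validate_patient({
    "patient_id": "EX-001",
    "sex": "female",
    "birth_date": "2006-04-12",
    "centers": ["C03"],
    "diagnoses": [{
        "date": "2019-03-01",
        "disease_category": "lymphoma",
        "cancer_rank": 1,
        "treatment_lines": [{
            "line_number": 1,
            "start_date": "2019-03-15",
            "end_date": "2019-10-20",
            "chemo_courses": [{
                "protocol_id": "HL-EuroNet", "arm_id": "OEPA",
                "start_date": "2019-03-15", "end_date": "2019-07-01",
                "agent_doses": [
                    {"agent": "doxorubicin", "cumulative_dose": 160, "source": "table_default"},
                    {"agent": "etoposide", "cumulative_dose": 2500, "source": "table_default"},
                    {"agent": "procarbazine", "cumulative_dose": 3000, "source": "table_default"},
                ],
            }],
            "rt_courses": [{
                "start_date": "2019-08-01", "end_date": "2019-09-10",
                "fields_irradiated": ["cervical"],
                "prescribed_dose": 25.0,
                "dosimetry_available": True,
                "organ_doses": [
                    {"organ": "thyroid", "mean_dose": 21.0},
                    {"organ": "salivary_glands", "mean_dose": 9.0},
                    {"organ": "carotid", "mean_dose": 18.0},
                ],
            }],
        }],
    }],
})

plan = generate_plan(patient, default_rulebase(), as_of=dt.date(2024, 6, 1))

print(f"{len(plan.items)} surveillance item(s) proposed for {plan.patient_id}:\n")
for item in plan.items:
    print(f"  {item.label}")
    print(f"    every {item.frequency.interval}, evidence: {item.evidence_level}, "
          f"data quality: {item.data_quality}")

# Each line is one recommendation the physician reviews (deselect / modify /
# add); the 'precise' data quality means every matched condition could be
# decided from the recorded exposures.
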