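"""Degraded mode: missing organ dosimetry never silently drops surveillance.

The same supra-diaphragmatic (chest) irradiation is evaluated twice.  With
organ dosimetry showing the breasts were spared (0.4 Gy), no breast imaging
is proposed.  Without dosimetry, the breast dose is UNKNOWN — not zero — so
breast imaging IS proposed, flagged 'degraded' with the missing facts listed.
"""

import datetime as dt

from survplan import default_rulebase, generate_plan, validate_patient


def patient(organ_doses):
    return validate_patient({
        "patient_id": "EX-002",
        "sex": "female",
        "birth_date": "2005-01-01",
        "centers": ["C01"],
        "diagnoses": [{
            "date": "2015-01-15",
            "disease_category": "lymphoma",
            "cancer_rank": 1,
            "treatment_lines": [{
                "line_number": 1,
                "start_date": "2015-02-01",
                "end_date": "2015-11-01",
                "rt_courses": [{
                    "start_date": "2015-05-01", "end_date": "2015-06-01",
                    "fields_irradiated": ["supra_diaphragmatic"],
                    "prescribed_dose": 25.0,
                    "dosimetry_available": bool(organ_doses),
                    "organ_doses": organ_doses,
                }],
            }],
        }],
    })


rb = default_rulebase()
as_of = dt.date(2024, 1, 1)

with_dosimetry = generate_plan(patient([
    {"organ": "breast", "mean_dose": 0.4},
    {"organ": "heart", "mean_dose": 1.0},
    {"organ": "lung", "mean_dose": 2.0},
    {"organ": "thyroid", "mean_dose": 1.0},
]), rb, as_of=as_of)
print("with dosimetry (breast spared, 0.4 Gy):")
print("  breast imaging proposed?", with_dosimetry.has_item("breast_imaging"))

without_dosimetry = generate_plan(patient([]), rb, as_of=as_of)
item = without_dosimetry.item("breast_imaging")
print("\nwithout dosimetry (field + prescribed dose only):")
print("  breast imaging proposed?", True)
print("  data quality:", item.data_quality)
print("  missing facts:", ", ".join(item.missing_data_notes))

# The conservative asymmetry is the point: absence of evidence of exposure
# is not treated as evidence of absence.
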