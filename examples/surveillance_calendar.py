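"""From plan to calendar: due dates, a pregnancy pause, notifications,
overdue detection and the permanent stop at long-term follow-up replanning.
"""

import datetime as dt

from survplan import (
    Modification,
    apply_modification,
    apply_pause,
    build_schedule,
    default_rulebase,
    flag_overdue,
    generate_plan,
    next_notifications,
    stop_schedule,
    validate_patient,
)
from survplan.rulebase import Duration

patient = validate_patient({
    "patient_id": "EX-003",
    "sex": "female",
    "birth_date": "2004-07-01",
    "centers": ["C02"],
    "diagnoses": [{
        "date": "2018-02-01",
        "disease_category": "sarcoma",
        "cancer_rank": 1,
        "treatment_lines": [{
            "line_number": 1,
            "start_date": "2018-02-15",
            "end_date": "2018-12-01",
            "chemo_courses": [{
                "protocol_id": "EWS-2008", "arm_id": "VIDE",
                "start_date": "2018-02-15", "end_date": "2018-09-01",
                "agent_doses": [
                    {"agent": "doxorubicin", "cumulative_dose": 360, "source": "table_default"},
                    {"agent": "ifosfamide", "cumulative_dose": 54000, "source": "table_default"},
                ],
            }],
        }],
    }],
})

plan = generate_plan(patient, default_rulebase(), as_of=dt.date(2019, 1, 1))
plan = apply_modification(plan, Modification(action="accept", endpoint_id="echocardiography"),
                          actor="dr_martin")

anchors = {"end_of_treatment": dt.date(2018, 12, 1),
           "diagnosis": dt.date(2018, 2, 1),
           "birth_date": dt.date(2004, 7, 1)}
schedule = build_schedule(plan, anchors, horizon=dt.date(2029, 1, 1))
print("echocardiography due dates:", [str(d) for d in schedule.due_dates("echocardiography")])

schedule = apply_pause(schedule, dt.date(2022, 6, 1), dt.date(2023, 4, 1), reason="pregnancy")
print("after pregnancy pause:     ", [str(d) for d in schedule.due_dates("echocardiography")])

due = next_notifications(schedule, (dt.date(2020, 1, 1), dt.date(2021, 12, 31)))
print(f"{len(due)} notification(s) in 2020-2021, sent to patient + attending physician")

late = flag_overdue(schedule, dt.date(2024, 6, 1), grace=Duration(months=3))
print(f"{len(late)} entry(ies) overdue on 2024-06-01 (due + 3-month grace elapsed)")

schedule = stop_schedule(schedule, "replanning: initial follow-up -> long-term follow-up")
print("after permanent stop, pending entries:",
      sum(1 for e in schedule.entries if e.status == "pending"))

# Pauses delay examinations instead of dropping them (shift-then-respace);
# the overdue list is how the care team spots patients drifting away from
# follow-up.
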