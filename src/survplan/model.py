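"""Structured treatment-summary data model for childhood/young-adult cancer
survivors.

A :class:`PatientRecord` captures one survivor's oncological history —
diagnoses, treatment lines (surgery, chemotherapy, radiotherapy, transplant,
supportive care), follow-up events, predisposition syndromes, lifestyle and
social data — in a form every other module (rule engine, planner, summary,
export, cohort tools) can consume.  Validation is strict: enumerations and
organ/field code lists are closed, dates are ISO-8601 calendar dates, and
inclusion requires an age below 25 years at first diagnosis.
"""

from __future__ import annotations

import datetime as dt
import json
from typing import Literal, Mapping, Optional, Union

from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from . import vocab

DAYS_PER_YEAR = 365.25

Sex = Literal["male", "female"]
VitalStatus = Literal["alive", "deceased"]

DiseaseCategory = Literal[
    "leukemia",
    "cerebral_tumor",
    "lymphoma",
    "sarcoma",
    "kidney_tumor",
    "neuroblastoma",
    "rare_tumor",
    "extra_cerebral_germ_cell_tumor",
    "other",
]

CarcinologicalImpact = Literal[
    "complete_resection", "microscopically_incomplete", "macroscopically_incomplete"
]
FunctionalImpact = Literal["none", "partial_removal", "complete_removal"]
DoseSource = Literal["table_default", "adapted"]
SupportiveCare = Literal["corticotherapy", "transfusion", "fertility_preservation", "other"]
EventType = Literal[
    "late_effect", "organ_loss", "chronic_pain", "chronic_fatigue", "aesthetic_sequela", "other"
]
OrganStatus = Literal["intact", "partially_removed", "removed", "unknown"]
YesNoUnknown = Literal["yes", "no", "unknown"]


def age_years(birth_date: dt.date, on: dt.date) -> float:
    """Exact age in years as (on - birth_date) / 365.25 days."""
    return (on - birth_date).days / DAYS_PER_YEAR


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)


class SurgeryRecord(_Model):
    date: dt.date
    organ: str
    carcinological_impact: CarcinologicalImpact
    functional_impact: FunctionalImpact

    @field_validator("organ")
    @classmethod
    def _organ_known(cls, v: str) -> str:
        if v not in vocab.organs():
            raise ValueError(f"unknown organ code {v!r}")
        return v


class AgentDose(_Model):
    agent: str
    cumulative_dose: float = Field(ge=0)
    units: Literal["mg/m2", "mg/kg"] = "mg/m2"
    source: DoseSource = "adapted"

    @field_validator("agent")
    @classmethod
    def _agent_known(cls, v: str) -> str:
        if v not in vocab.agents():
            raise ValueError(f"unknown agent {v!r}")
        return v


class ChemoCourse(_Model):
    protocol_id: str
    arm_id: str
    start_date: dt.date
    end_date: dt.date
    agent_doses: tuple[AgentDose, ...] = ()
    hsct_conditioning: bool = False

    @model_validator(mode="after")
    def _dates_ordered(self) -> "ChemoCourse":
        if self.end_date < self.start_date:
            raise ValueError("chemo course end_date before start_date")
        return self


class OrganDose(_Model):
    organ: str
    mean_dose: float = Field(ge=0, description="mean organ dose in Gy")
    max_dose: Optional[float] = None

    @field_validator("organ")
    @classmethod
    def _organ_known(cls, v: str) -> str:
        if v not in vocab.organs():
            raise ValueError(f"unknown organ code {v!r}")
        return v

    @model_validator(mode="after")
    def _max_ge_mean(self) -> "OrganDose":
        if self.max_dose is not None and self.max_dose < self.mean_dose:
            raise ValueError("max_dose below mean_dose")
        return self


class RadiotherapyCourse(_Model):
    start_date: dt.date
    end_date: dt.date
    fields_irradiated: tuple[str, ...] = Field(min_length=1)
    prescribed_dose: float = Field(gt=0, description="prescribed dose in Gy")
    organ_doses: tuple[OrganDose, ...] = ()
    dosimetry_available: bool = False

    @field_validator("fields_irradiated")
    @classmethod
    def _fields_known(cls, v: tuple[str, ...]) -> tuple[str, ...]:
        bad = [f for f in v if f not in vocab.fields()]
        if bad:
            raise ValueError(f"unknown field code(s) {bad}")
        return v

    @model_validator(mode="after")
    def _dosimetry_flag(self) -> "RadiotherapyCourse":
        if self.end_date < self.start_date:
            raise ValueError("radiotherapy end_date before start_date")
        if self.dosimetry_available != bool(self.organ_doses):
            raise ValueError("dosimetry_available must be true iff organ_doses present")
        return self


class HSCTRecord(_Model):
    date: dt.date
    graft: Literal["autograft", "allograft"]


class Anthropometry(_Model):
    height_cm: float = Field(gt=0)
    weight_kg: float = Field(gt=0)


class TreatmentLine(_Model):
    """One treatment line; line 1 is first-line, lines >= 2 treat recurrences.

    A line with no surgery, chemotherapy, radiotherapy or transplant is
    'simple monitoring'.
    """

    line_number: int = Field(ge=1)
    start_date: dt.date
    end_date: dt.date
    surgeries: tuple[SurgeryRecord, ...] = ()
    chemo_courses: tuple[ChemoCourse, ...] = ()
    rt_courses: tuple[RadiotherapyCourse, ...] = ()
    hsct: Optional[HSCTRecord] = None
    supportive_care: tuple[SupportiveCare, ...] = ()
    anthropometry_start: Optional[Anthropometry] = None
    anthropometry_end: Optional[Anthropometry] = None

    @model_validator(mode="after")
    def _dates_ordered(self) -> "TreatmentLine":
        if self.end_date < self.start_date:
            raise ValueError("treatment line end_date before start_date")
        return self

    @property
    def is_simple_monitoring(self) -> bool:
        return not (self.surgeries or self.chemo_courses or self.rt_courses or self.hsct)


class DiagnosisEvent(_Model):
    date: dt.date
    disease_category: DiseaseCategory
    cancer_rank: int = Field(ge=1)
    treatment_lines: tuple[TreatmentLine, ...] = Field(min_length=1)
    tumor_bank_sample: bool = False

    @model_validator(mode="after")
    def _lines_numbered(self) -> "DiagnosisEvent":
        numbers = [ln.line_number for ln in self.treatment_lines]
        if numbers != list(range(1, len(numbers) + 1)):
            raise ValueError(f"treatment lines must be numbered 1..k without gaps, got {numbers}")
        return self


class FollowUpEvent(_Model):
    date: dt.date
    organ_category: str
    event_type: EventType
    organ: Optional[str] = None
    ctcae_grade: Optional[int] = Field(default=None, ge=1, le=5)
    description: str = ""

    @field_validator("organ_category")
    @classmethod
    def _system_known(cls, v: str) -> str:
        if v not in vocab.organ_systems():
            raise ValueError(f"unknown organ-system code {v!r}")
        return v

    @model_validator(mode="after")
    def _organ_loss_names_organ(self) -> "FollowUpEvent":
        if self.organ is not None and self.organ not in vocab.organs():
            raise ValueError(f"unknown organ code {self.organ!r}")
        if self.event_type == "organ_loss" and self.organ is None:
            raise ValueError("organ_loss events must name the lost organ")
        return self


class PredispositionSyndrome(_Model):
    name: str
    gene: Optional[str] = None
    confirmed: bool = False


class LifestyleData(_Model):
    smoking_status: YesNoUnknown = "unknown"
    cannabis_use: YesNoUnknown = "unknown"
    unhealthy_alcohol_use: YesNoUnknown = "unknown"
    physical_activity: Literal["none", "occasional", "regular", "unknown"] = "unknown"


class SocialData(_Model):
    current_class_or_occupation: str = ""
    sports_practice: YesNoUnknown = "unknown"


class PatientRecord(_Model):
    patient_id: str = Field(min_length=1)
    sex: Sex
    birth_date: dt.date
    vital_status: VitalStatus = "alive"
    centers: tuple[str, ...] = Field(min_length=1)
    diagnoses: tuple[DiagnosisEvent, ...] = Field(min_length=1)
    follow_up_events: tuple[FollowUpEvent, ...] = ()
    predispositions: tuple[PredispositionSyndrome, ...] = ()
    comorbidities: tuple[str, ...] = ()
    lifestyle: LifestyleData = LifestyleData()
    social: SocialData = SocialData()
    residence_unit: Optional[str] = None
    edi_quintile: Optional[Union[int, Literal["unknown"]]] = None
    consent_research: bool = True

    @model_validator(mode="after")
    def _invariants(self) -> "PatientRecord":
        dates = [d.date for d in self.diagnoses]
        if dates != sorted(dates):
            raise ValueError("diagnoses must be ordered by date")
        for d in self.diagnoses:
            if d.date < self.birth_date:
                raise ValueError("diagnosis date before birth_date")
        if age_years(self.birth_date, self.diagnoses[0].date) >= 25.0:
            raise ValueError(
                "inclusion: age at first diagnosis must be under 25 years, got "
                f"{age_years(self.birth_date, self.diagnoses[0].date):.1f}"
            )
        return self

    @property
    def first_diagnosis(self) -> DiagnosisEvent:
        return self.diagnoses[0]

    def age_at(self, on: dt.date) -> float:
        return age_years(self.birth_date, on)


def validate_patient(record: Union[Mapping, PatientRecord]) -> PatientRecord:
    """Validate a raw mapping (parsed JSON/YAML) into a typed PatientRecord.

    Idempotent: validating an already-valid record returns an equal record.
    Raises pydantic.ValidationError naming the offending field; records whose
    age at first diagnosis is >= 25 years violate the inclusion rule.
    """
    if isinstance(record, PatientRecord):
        record = record.model_dump(mode="json")
    return PatientRecord.model_validate(record)


_STATUS_RANK = {"intact": 0, "unknown": 1, "partially_removed": 2, "removed": 3}


def derive_organ_status(patient: PatientRecord, as_of: dt.date) -> dict[str, OrganStatus]:
    """Per-organ anatomical status at a given date.

    An organ is ``removed`` iff any surgery with functional_impact
    complete_removal, or any organ_loss follow-up event, names it on or
    before ``as_of``; ``partially_removed`` ranks below ``removed``; organs
    never mentioned are ``intact``.  Monotone in time: once removed, removed
    for every later date.
    """
    status: dict[str, OrganStatus] = {organ: "intact" for organ in vocab.organs()}

    def upgrade(organ: str, new: OrganStatus) -> None:
        if _STATUS_RANK[new] > _STATUS_RANK[status[organ]]:
            status[organ] = new

    for diag in patient.diagnoses:
        for line in diag.treatment_lines:
            for surg in line.surgeries:
                if surg.date > as_of:
                    continue
                if surg.functional_impact == "complete_removal":
                    upgrade(surg.organ, "removed")
                elif surg.functional_impact == "partial_removal":
                    upgrade(surg.organ, "partially_removed")
    for ev in patient.follow_up_events:
        if ev.event_type == "organ_loss" and ev.organ is not None and ev.date <= as_of:
            upgrade(ev.organ, "removed")
    return status


def patient_json_schema() -> dict:
    """JSON-Schema document for the patient record format."""
    return PatientRecord.model_json_schema()


def to_json(patient: PatientRecord, **kwargs) -> str:
    return json.dumps(patient.model_dump(mode="json"), **kwargs)


def from_json(text: str) -> PatientRecord:
    return validate_patient(json.loads(text))
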