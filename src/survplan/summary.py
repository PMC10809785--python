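"""Harmonized treatment summaries, theoretical dose resolution, and
pseudonymized cohort export.

``resolve_cumulative_doses`` looks up the theoretical cumulative doses a
protocol arm prescribes (limiting transcription errors) and lets sites adapt
individual agents; ``render_treatment_summary`` produces the one-document
oncological history deposited in the medical record; ``export_cohort``
produces research tables in which patient identifiers are replaced by
generated (keyed, random) pseudonyms and direct identifiers are minimized
(birth date exported as year only).
"""

from __future__ import annotations

import datetime as dt
import hashlib
import json
import random
import string
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from .model import PatientRecord

TOKEN_LENGTH = 12
_TOKEN_ALPHABET = string.ascii_uppercase + string.digits


class DoseTableError(KeyError):
    pass


@dataclass(frozen=True)
class DoseEntry:
    agent: str
    cumulative_dose: float
    units: str
    source: str  # table_default | adapted


@dataclass
class DoseTable:
    """(protocol, arm) -> theoretical cumulative doses per agent."""

    version: str
    table: dict[tuple[str, str], tuple[DoseEntry, ...]]

    @classmethod
    def from_csv(cls, path: Union[str, Path], version: str = "") -> "DoseTable":
        df = pd.read_csv(path)
        required = {"protocol", "arm", "agent", "cumulative_dose", "units"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"dose table missing columns {sorted(missing)}")
        if (df["cumulative_dose"] <= 0).any():
            raise ValueError("dose table doses must be > 0")
        dup = df.duplicated(subset=["protocol", "arm", "agent"])
        if dup.any():
            raise ValueError("duplicate (protocol, arm, agent) rows in dose table")
        table: dict[tuple[str, str], list[DoseEntry]] = {}
        for row in df.itertuples(index=False):
            table.setdefault((row.protocol, row.arm), []).append(
                DoseEntry(
                    agent=row.agent,
                    cumulative_dose=float(row.cumulative_dose),
                    units=row.units,
                    source="table_default",
                )
            )
        return cls(version=version or str(Path(path).stem), table={k: tuple(v) for k, v in table.items()})

    def arms(self) -> list[tuple[str, str]]:
        return sorted(self.table)

    def lookup(self, protocol: str, arm: str) -> tuple[DoseEntry, ...]:
        try:
            return self.table[(protocol, arm)]
        except KeyError:
            raise DoseTableError(f"unknown protocol/arm ({protocol!r}, {arm!r})") from None


@lru_cache(maxsize=1)
def default_dose_table() -> DoseTable:
    with resources.files("survplan.data").joinpath("dose_table.csv").open() as fh:
        import io

        return DoseTable.from_csv(io.StringIO(fh.read()), version="packaged-2024.1")


def resolve_cumulative_doses(
    protocol: str,
    arm: str,
    adaptations: Sequence[tuple[str, float]] = (),
    dose_table: Optional[DoseTable] = None,
) -> tuple[list[DoseEntry], list[str]]:
    """Theoretical doses for a protocol arm, with per-agent adaptations.

    Returns (entries, warnings).  Table agents come back with
    source=table_default; an adapted agent overrides the table value with
    source=adapted; adapting an agent absent from the arm emits a warning
    but the agent is still included.
    """
    table = dose_table or default_dose_table()
    defaults = table.lookup(protocol, arm)
    adapted = dict(adaptations)
    warnings: list[str] = []
    out: list[DoseEntry] = []
    for entry in defaults:
        if entry.agent in adapted:
            out.append(
                DoseEntry(
                    agent=entry.agent,
                    cumulative_dose=float(adapted.pop(entry.agent)),
                    units=entry.units,
                    source="adapted",
                )
            )
        else:
            out.append(entry)
    for agent, dose in adapted.items():
        warnings.append(f"adaptation for agent {agent!r} not in arm ({protocol}, {arm}); included")
        from . import vocab

        out.append(
            DoseEntry(agent=agent, cumulative_dose=float(dose), units=vocab.default_units(agent), source="adapted")
        )
    return out, warnings


# --------------------------------------------------------------------------
# Harmonized treatment summary


def summarize_patient(patient: PatientRecord) -> dict:
    """Structured (JSON-ready) treatment summary covering every line."""
    agent_totals: dict[str, dict] = {}
    lines_out = []
    for diag in patient.diagnoses:
        for line in diag.treatment_lines:
            surgeries = [
                {
                    "date": s.date.isoformat(),
                    "organ": s.organ,
                    "carcinological_impact": s.carcinological_impact,
                    "functional_impact": s.functional_impact,
                }
                for s in line.surgeries
            ]
            chemo = []
            for course in line.chemo_courses:
                for ad in course.agent_doses:
                    key = ad.agent
                    tot = agent_totals.setdefault(key, {"dose": 0.0, "units": ad.units})
                    tot["dose"] += ad.cumulative_dose
                chemo.append(
                    {
                        "protocol": course.protocol_id,
                        "arm": course.arm_id,
                        "agents": [
                            {"agent": a.agent, "dose": a.cumulative_dose, "units": a.units, "source": a.source}
                            for a in course.agent_doses
                        ],
                    }
                )
            rt = [
                {
                    "fields": list(c.fields_irradiated),
                    "prescribed_dose_gy": c.prescribed_dose,
                    "dosimetry_available": c.dosimetry_available,
                    "organ_doses": [
                        {"organ": od.organ, "mean_dose_gy": od.mean_dose} for od in c.organ_doses
                    ],
                }
                for c in line.rt_courses
            ]
            lines_out.append(
                {
                    "diagnosis_date": diag.date.isoformat(),
                    "disease_category": diag.disease_category,
                    "cancer_rank": diag.cancer_rank,
                    "line_number": line.line_number,
                    "simple_monitoring": line.is_simple_monitoring,
                    "surgeries": surgeries,
                    "chemotherapy": chemo,
                    "radiotherapy": rt,
                    "hsct": None if line.hsct is None else {"date": line.hsct.date.isoformat(), "graft": line.hsct.graft},
                    "supportive_care": list(line.supportive_care),
                }
            )
    return {
        "patient_id": patient.patient_id,
        "sex": patient.sex,
        "birth_date": patient.birth_date.isoformat(),
        "diagnoses": [
            {
                "date": d.date.isoformat(),
                "disease_category": d.disease_category,
                "cancer_rank": d.cancer_rank,
                "tumor_bank_sample": d.tumor_bank_sample,
                "n_treatment_lines": len(d.treatment_lines),
            }
            for d in patient.diagnoses
        ],
        "treatment_lines": lines_out,
        "cumulative_agent_doses": {
            agent: {"dose": round(v["dose"], 6), "units": v["units"]}
            for agent, v in sorted(agent_totals.items())
        },
        "second_cancers": sum(1 for d in patient.diagnoses if d.cancer_rank >= 2),
        "recurrence_lines": sum(
            1 for d in patient.diagnoses for ln in d.treatment_lines if ln.line_number >= 2
        ),
        "predispositions": [p.name for p in patient.predispositions],
    }


def render_treatment_summary(patient: PatientRecord) -> str:
    """Markdown rendering of the harmonized oncological-history summary."""
    doc = summarize_patient(patient)
    md = [f"# Treatment summary — patient {doc['patient_id']}", ""]
    md.append(f"Sex: {doc['sex']}; born {doc['birth_date']}.")
    md.append("")
    md.append("## Diagnoses")
    for d in doc["diagnoses"]:
        rank = "first cancer" if d["cancer_rank"] == 1 else f"cancer #{d['cancer_rank']}"
        bank = "tumor-bank sample available" if d["tumor_bank_sample"] else "no tumor-bank sample"
        md.append(f"- {d['date']}: {d['disease_category'].replace('_', ' ')} ({rank}; {bank})")
    md.append("")
    md.append("## Treatment lines")
    for line in doc["treatment_lines"]:
        md.append(f"### Line {line['line_number']} ({line['disease_category'].replace('_', ' ')})")
        if line["simple_monitoring"]:
            md.append("- surveillance only (no oncological treatment)")
            md.append("")
            continue
        for s in line["surgeries"]:
            md.append(
                f"- surgery {s['date']}: {s['organ']} — {s['carcinological_impact'].replace('_', ' ')}, "
                f"functional impact: {s['functional_impact'].replace('_', ' ')}"
            )
        for c in line["chemotherapy"]:
            agents = ", ".join(f"{a['agent']} {a['dose']:g} {a['units']}" for a in c["agents"])
            md.append(f"- chemotherapy {c['protocol']}/{c['arm']}: {agents}")
        for r in line["radiotherapy"]:
            fields = ", ".join(r["fields"])
            if r["dosimetry_available"]:
                organs = "; ".join(
                    f"{od['organ']} {od['mean_dose_gy']:g} Gy" for od in r["organ_doses"]
                )
                md.append(
                    f"- radiotherapy ({fields}), prescribed {r['prescribed_dose_gy']:g} Gy; organ doses: {organs}"
                )
            else:
                md.append(
                    f"- radiotherapy ({fields}), prescribed {r['prescribed_dose_gy']:g} Gy; "
                    "precise dosimetric data are missing"
                )
        if line["hsct"]:
            md.append(f"- HSCT {line['hsct']['date']} ({line['hsct']['graft']})")
        if line["supportive_care"]:
            md.append("- supportive care: " + ", ".join(line["supportive_care"]))
        md.append("")
    if doc["cumulative_agent_doses"]:
        md.append("## Cumulative chemotherapy doses (all lines)")
        for agent, v in doc["cumulative_agent_doses"].items():
            md.append(f"- {agent}: {v['dose']:g} {v['units']}")
        md.append("")
    if doc["second_cancers"]:
        md.append(f"Second cancers registered: {doc['second_cancers']}.")
    if doc["recurrence_lines"]:
        md.append(f"Recurrence treatment lines registered: {doc['recurrence_lines']}.")
    return "\n".join(md)


# --------------------------------------------------------------------------
# Pseudonymization and cohort export


@dataclass
class PseudonymMap:
    """Keyed map patient_id -> generated 12-character identifier.

    Identifiers are random tokens drawn from a generator seeded by the
    secret key — they carry no information from the patient identifier, and
    re-identification requires this map.  Assignment is stable: exporting
    twice with the same map (or the same key and cohort order) yields the
    same pseudonyms.
    """

    key: str
    mapping: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seed = int.from_bytes(hashlib.sha256(self.key.encode()).digest()[:8], "big")
        self._rng = random.Random(seed)
        self._used = set(self.mapping.values())

    def assign(self, patient_id: str) -> str:
        if patient_id in self.mapping:
            return self.mapping[patient_id]
        while True:
            token = "".join(self._rng.choices(_TOKEN_ALPHABET, k=TOKEN_LENGTH))
            if token not in self._used:
                break
        self.mapping[patient_id] = token
        self._used.add(token)
        return token

    def save(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps({"key": self.key, "mapping": self.mapping}, indent=1))

    @classmethod
    def load(cls, path: Union[str, Path]) -> "PseudonymMap":
        doc = json.loads(Path(path).read_text())
        return cls(key=doc["key"], mapping=dict(doc["mapping"]))


@dataclass
class CohortExport:
    patients: pd.DataFrame
    treatments: pd.DataFrame
    events: pd.DataFrame
    manifest: dict


PATIENT_COLUMNS = (
    "pseudonym",
    "sex",
    "birth_year",
    "vital_status",
    "age_at_first_diagnosis",
    "first_disease_category",
    "n_diagnoses",
    "n_treatment_lines",
    "surgery_first_line",
    "medical_treatment_first_line",
    "radiotherapy_first_line",
    "hsct",
    "tumor_bank_sample",
    "n_second_cancers",
    "n_recurrence_lines",
    "edi_quintile",
)


def export_cohort(
    patients: Iterable[PatientRecord],
    pseudonym_map: PseudonymMap,
    field_selection: Optional[Sequence[str]] = None,
    consent_override_ids: Sequence[str] = (),
) -> CohortExport:
    """Pseudonymized research export: one patient-level table plus long
    tables for treatments and follow-up events.

    Patients without research consent are excluded (and counted in the
    manifest) unless listed in ``consent_override_ids``.  Direct identifiers
    are minimized: the patient identifier is replaced by the generated
    pseudonym and the birth date is exported as birth year only, with ages
    pre-computed.
    """
    columns = list(field_selection) if field_selection else list(PATIENT_COLUMNS)
    unknown = set(columns) - set(PATIENT_COLUMNS)
    if unknown:
        raise ValueError(f"unknown export fields {sorted(unknown)}")
    if "pseudonym" not in columns:
        columns.insert(0, "pseudonym")

    rows, treat_rows, event_rows = [], [], []
    excluded = 0
    for patient in patients:
        if not patient.consent_research and patient.patient_id not in consent_override_ids:
            excluded += 1
            continue
        token = pseudonym_map.assign(patient.patient_id)
        first = patient.first_diagnosis
        first_line = first.treatment_lines[0]
        rows.append(
            {
                "pseudonym": token,
                "sex": patient.sex,
                "birth_year": patient.birth_date.year,
                "vital_status": patient.vital_status,
                "age_at_first_diagnosis": round(patient.age_at(first.date), 2),
                "first_disease_category": first.disease_category,
                "n_diagnoses": len(patient.diagnoses),
                "n_treatment_lines": sum(len(d.treatment_lines) for d in patient.diagnoses),
                "surgery_first_line": bool(first_line.surgeries),
                "medical_treatment_first_line": bool(first_line.chemo_courses),
                "radiotherapy_first_line": bool(first_line.rt_courses),
                "hsct": any(
                    ln.hsct is not None for d in patient.diagnoses for ln in d.treatment_lines
                ),
                "tumor_bank_sample": any(d.tumor_bank_sample for d in patient.diagnoses),
                "n_second_cancers": sum(1 for d in patient.diagnoses if d.cancer_rank >= 2),
                "n_recurrence_lines": sum(
                    1 for d in patient.diagnoses for ln in d.treatment_lines if ln.line_number >= 2
                ),
                "edi_quintile": patient.edi_quintile if patient.edi_quintile is not None else "unknown",
            }
        )
        for diag in patient.diagnoses:
            for line in diag.treatment_lines:
                modalities = []
                if line.surgeries:
                    modalities.append("surgery")
                if line.chemo_courses:
                    modalities.append("medical_treatment")
                if line.rt_courses:
                    modalities.append("radiotherapy")
                if line.hsct is not None:
                    modalities.append(f"hsct_{line.hsct.graft}")
                if not modalities:
                    modalities.append("simple_monitoring")
                treat_rows.append(
                    {
                        "pseudonym": token,
                        "cancer_rank": diag.cancer_rank,
                        "disease_category": diag.disease_category,
                        "line_number": line.line_number,
                        "age_at_line_start": round(patient.age_at(line.start_date), 2),
                        "modalities": "|".join(modalities),
                    }
                )
        for ev in patient.follow_up_events:
            event_rows.append(
                {
                    "pseudonym": token,
                    "age_at_event": round(patient.age_at(ev.date), 2),
                    "organ_category": ev.organ_category,
                    "event_type": ev.event_type,
                    "ctcae_grade": ev.ctcae_grade,
                }
            )

    patients_df = pd.DataFrame(rows, columns=columns)
    manifest = {
        "exported": len(rows),
        "excluded_no_consent": excluded,
        "fields": columns,
        "pseudonym_length": TOKEN_LENGTH,
        "exported_at": dt.date.today().isoformat(),
    }
    return CohortExport(
        patients=patients_df,
        treatments=pd.DataFrame(
            treat_rows,
            columns=[
                "pseudonym",
                "cancer_rank",
                "disease_category",
                "line_number",
                "age_at_line_start",
                "modalities",
            ],
        ),
        events=pd.DataFrame(
            event_rows,
            columns=["pseudonym", "age_at_event", "organ_category", "event_type", "ctcae_grade"],
        ),
        manifest=manifest,
    )
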