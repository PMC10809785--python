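"""Personalized survivorship care plan (PSCP) generation.

The engine derives a fact set from a validated patient record (cumulative
agent doses, per-organ radiation doses, irradiated fields, organ status,
predispositions, comorbidities, demographics), evaluates every rule-base
condition under strong Kleene three-valued logic, and assembles an auditable
surveillance plan.

Missing-data behaviour ("degraded mode"): when a radiotherapy course has no
organ-level dosimetry, the mean dose of every organ potentially exposed by
its fields is UNKNOWN — not zero.  A condition that cannot be decided then
evaluates UNKNOWN and still triggers its endpoint, flagged ``degraded`` with
the missing fact keys listed, so surveillance is proposed conservatively
with an explicit caveat rather than silently dropped.  Organs lying in no
irradiated field have dose 0.  Endpoints targeting a surgically removed
organ are suppressed (e.g. no thyroid second-tumor surveillance after
thyroidectomy), with the suppression reason logged.
"""

from __future__ import annotations

import copy
import csv
import datetime as dt
import enum
import json
from dataclasses import dataclass, field, replace
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Any, Optional, Union

from . import vocab
from .model import PatientRecord, derive_organ_status
from .rulebase import (
    And,
    Condition,
    Duration,
    EVIDENCE_LEVELS,
    Endpoint,
    FactAtom,
    FrequencySpec,
    GuidelineRuleBase,
    Leaf,
    Not,
    Or,
    Predicate,
    iter_leaves,
)


class _Unknown:
    """Singleton marker for a missing fact value."""

    _instance: Optional["_Unknown"] = None

    def __new__(cls) -> "_Unknown":
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "UNKNOWN"

    def __bool__(self) -> bool:
        raise TypeError("UNKNOWN has no truth value; use three-valued logic")


UNKNOWN = _Unknown()


class K3(enum.Enum):
    """Strong Kleene three-valued truth value."""

    FALSE = 0
    UNKNOWN = 1
    TRUE = 2

    def __and__(self, other: "K3") -> "K3":
        return K3(min(self.value, other.value))

    def __or__(self, other: "K3") -> "K3":
        return K3(max(self.value, other.value))

    def __invert__(self) -> "K3":
        return K3(2 - self.value)

    @classmethod
    def from_bool(cls, b: bool) -> "K3":
        return cls.TRUE if b else cls.FALSE


# --------------------------------------------------------------------------
# Exposure map


@lru_cache(maxsize=1)
def default_exposure_map() -> dict[str, frozenset[str]]:
    with resources.files("survplan.data").joinpath("exposure_map.csv").open() as fh:
        return _parse_exposure_rows(csv.DictReader(fh))


def load_exposure_map(path: Union[str, Path]) -> dict[str, frozenset[str]]:
    """Field -> potentially exposed organs; a '*' organ row means all organs."""
    with open(path, newline="") as fh:
        return _parse_exposure_rows(csv.DictReader(fh))


def _parse_exposure_rows(rows) -> dict[str, frozenset[str]]:
    acc: dict[str, set[str]] = {}
    for row in rows:
        fld, organ = row["field"].strip(), row["organ"].strip()
        if fld not in vocab.fields():
            raise ValueError(f"exposure map references unknown field code {fld!r}")
        if organ == "*":
            acc.setdefault(fld, set()).update(vocab.organs())
            continue
        if organ not in vocab.organs():
            raise ValueError(f"exposure map references unknown organ code {organ!r}")
        acc.setdefault(fld, set()).add(organ)
    return {f: frozenset(o) for f, o in acc.items()}


# --------------------------------------------------------------------------
# Fact derivation


FactValue = Union[float, bool, str, _Unknown]


@dataclass
class FactSet:
    """Map fact_key -> typed value or UNKNOWN, with per-fact provenance.

    Facts not stored explicitly resolve to closed-world defaults: doses 0,
    boolean facts False, organ status intact.
    """

    values: dict[str, FactValue] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)

    _DEFAULTS: tuple[tuple[str, FactValue], ...] = (
        ("organ_mean_dose", 0.0),
        ("field_irradiated", False),
        ("cumulative_dose", 0.0),
        ("predisposition", False),
        ("organ_status", "intact"),
        ("hsct_received", False),
        ("hsct_allograft", False),
        ("comorbidity", False),
        ("supportive_care", False),
    )

    def set(self, fact: str, arg: Optional[str], value: FactValue, provenance: str) -> None:
        key = fact if arg is None else f"{fact}({arg})"
        self.values[key] = value
        self.provenance[key] = provenance

    def get(self, fact: str, arg: Optional[str] = None) -> FactValue:
        key = fact if arg is None else f"{fact}({arg})"
        if key in self.values:
            return self.values[key]
        for prefix, default in self._DEFAULTS:
            if fact == prefix:
                return default
        raise KeyError(f"fact {key!r} not present and has no default")

    def resolve(self, atom: FactAtom) -> FactValue:
        return self.get(atom.fact, atom.arg)


def derive_facts(
    patient: PatientRecord,
    field_exposure_map: Optional[dict[str, frozenset[str]]] = None,
    as_of: Optional[dt.date] = None,
) -> FactSet:
    """Derive the evaluable fact set for one patient.

    Cumulative agent doses sum over every chemotherapy course of every line;
    per-organ mean radiation doses follow the degraded-mode convention
    described in the module docstring.  Raises ValueError for an irradiated
    field code absent from the exposure map.
    """
    exposure = field_exposure_map if field_exposure_map is not None else default_exposure_map()
    if as_of is None:
        as_of = max(
            line.end_date for diag in patient.diagnoses for line in diag.treatment_lines
        )

    facts = FactSet()
    facts.set("sex", None, patient.sex, "recorded")
    facts.set("age_at_diagnosis", None, patient.age_at(patient.first_diagnosis.date), "derived")
    first_line_start = patient.first_diagnosis.treatment_lines[0].start_date
    facts.set("age_at_treatment", None, patient.age_at(first_line_start), "derived")

    # cumulative chemotherapy doses, summed across all lines and courses
    totals: dict[str, float] = {}
    hsct_received = False
    hsct_allograft = False
    irradiated_fields: set[str] = set()
    recorded_dose: dict[str, float] = {}
    exposed_known: set[str] = set()  # organs in a field of a course WITH dosimetry
    exposed_unknown: set[str] = set()  # organs in a field of a course WITHOUT dosimetry
    supportive: set[str] = set()

    for diag in patient.diagnoses:
        for line in diag.treatment_lines:
            supportive.update(line.supportive_care)
            if line.hsct is not None:
                hsct_received = True
                hsct_allograft = hsct_allograft or line.hsct.graft == "allograft"
            for course in line.chemo_courses:
                for ad in course.agent_doses:
                    totals[ad.agent] = totals.get(ad.agent, 0.0) + ad.cumulative_dose
            for rt in line.rt_courses:
                for fld in rt.fields_irradiated:
                    if fld not in exposure:
                        raise ValueError(f"field code {fld!r} missing from exposure map")
                    irradiated_fields.add(fld)
                    target = exposed_known if rt.dosimetry_available else exposed_unknown
                    target.update(exposure[fld])
                for od in rt.organ_doses:
                    recorded_dose[od.organ] = recorded_dose.get(od.organ, 0.0) + od.mean_dose

    for agent, total in totals.items():
        facts.set("cumulative_dose", agent, total, "recorded")
    for fld in vocab.fields():
        facts.set("field_irradiated", fld, fld in irradiated_fields, "recorded")
    for organ in vocab.organs():
        if organ in exposed_unknown:
            # a course without dosimetry may have exposed this organ: the
            # true cumulative dose is unknowable, even if other courses
            # recorded a partial value
            facts.set("organ_mean_dose", organ, UNKNOWN, "missing")
        elif organ in recorded_dose:
            facts.set("organ_mean_dose", organ, recorded_dose[organ], "recorded")
        else:
            facts.set("organ_mean_dose", organ, 0.0, "derived")

    for organ, status in derive_organ_status(patient, as_of).items():
        facts.set("organ_status", organ, status, "derived")
    facts.set("hsct_received", None, hsct_received, "recorded")
    facts.set("hsct_allograft", None, hsct_allograft, "recorded")
    for kind in supportive:
        facts.set("supportive_care", kind, True, "recorded")
    for pre in patient.predispositions:
        facts.set("predisposition", pre.name, True, "recorded")
    for code in patient.comorbidities:
        facts.set("comorbidity", code, True, "recorded")
    return facts


# --------------------------------------------------------------------------
# Predicate evaluation (strong Kleene)


def _eval_atom(atom: FactAtom, facts: FactSet) -> K3:
    v = facts.resolve(atom)
    if v is UNKNOWN:
        return K3.UNKNOWN
    if atom.op == "==":
        return K3.from_bool(v == atom.value)
    if atom.op == "!=":
        return K3.from_bool(v != atom.value)
    if atom.op == "in":
        return K3.from_bool(v in atom.value)
    if not isinstance(v, (int, float)) or isinstance(v, bool):
        raise TypeError(
            f"comparator {atom.op!r} applied to non-numeric fact {atom.key} = {v!r}"
        )
    if atom.op == ">=":
        return K3.from_bool(v >= float(atom.value))
    if atom.op == "<=":
        return K3.from_bool(v <= float(atom.value))
    raise ValueError(f"unknown comparator {atom.op!r}")


def eval_predicate(predicate: Predicate, facts: FactSet) -> K3:
    """Evaluate an expression tree under strong Kleene semantics.

    A comparison with an UNKNOWN operand is UNKNOWN; AND is the minimum and
    OR the maximum over {FALSE < UNKNOWN < TRUE}; NOT swaps TRUE and FALSE
    and fixes UNKNOWN.
    """
    if isinstance(predicate, Leaf):
        return _eval_atom(predicate.atom, facts)
    if isinstance(predicate, And):
        out = K3.TRUE
        for child in predicate.children:
            out = out & eval_predicate(child, facts)
        return out
    if isinstance(predicate, Or):
        out = K3.FALSE
        for child in predicate.children:
            out = out | eval_predicate(child, facts)
        return out
    return ~eval_predicate(predicate.child, facts)


def unknown_fact_keys(predicate: Predicate, facts: FactSet) -> list[str]:
    """Fact keys referenced by the predicate whose value is UNKNOWN."""
    keys = []
    for atom in iter_leaves(predicate):
        if facts.resolve(atom) is UNKNOWN and atom.key not in keys:
            keys.append(atom.key)
    return keys


# --------------------------------------------------------------------------
# Plan objects


@dataclass
class PlanItem:
    endpoint_id: str
    label: str
    kind: str
    matched_conditions: tuple[tuple[str, str], ...]  # (condition_id, K3 name)
    frequency: FrequencySpec
    evidence_level: str
    data_quality: str  # precise | degraded
    missing_data_notes: tuple[str, ...] = ()
    status: str = "proposed"  # proposed | accepted | removed | modified
    cause: str = "rule_triggered"  # rule_triggered | physician_added
    notes: str = ""


@dataclass
class AuditEntry:
    timestamp: dt.datetime
    actor: str
    action: str  # deselect | modify_frequency | add_endpoint | accept | annotate
    endpoint_id: str
    params: dict
    before: Optional[dict]
    after: Optional[dict]


@dataclass
class SurveillancePlan:
    patient_id: str
    generated_at: dt.date
    rulebase_version: str
    items: list[PlanItem] = field(default_factory=list)
    suppressed: list[dict] = field(default_factory=list)
    audit_log: list[AuditEntry] = field(default_factory=list)

    def item(self, endpoint_id: str) -> PlanItem:
        for it in self.items:
            if it.endpoint_id == endpoint_id:
                return it
        raise KeyError(f"no plan item for endpoint {endpoint_id!r}")

    def has_item(self, endpoint_id: str) -> bool:
        return any(it.endpoint_id == endpoint_id for it in self.items)


def _evidence_rank(level: str) -> int:
    # high is strongest; expert_consensus ranks below very_low
    return len(EVIDENCE_LEVELS) - EVIDENCE_LEVELS.index(level)


def _build_item(endpoint: Endpoint, facts: FactSet) -> Optional[PlanItem]:
    verdicts: list[tuple[Condition, K3]] = [
        (c, eval_predicate(c.predicate, facts)) for c in endpoint.conditions
    ]
    matched = [(c, v) for c, v in verdicts if v is not K3.FALSE]
    if not matched:
        return None
    # most protective merge: shortest interval, strongest evidence
    frequency = min((c.frequency for c, _ in matched), key=lambda f: f.interval.sort_key)
    evidence = max((c.evidence_level for c, _ in matched), key=_evidence_rank)
    missing: list[str] = []
    degraded = False
    for c, v in matched:
        if v is K3.UNKNOWN:
            degraded = True
            for key in unknown_fact_keys(c.predicate, facts):
                if key not in missing:
                    missing.append(key)
    return PlanItem(
        endpoint_id=endpoint.endpoint_id,
        label=endpoint.label,
        kind=endpoint.kind,
        matched_conditions=tuple((c.condition_id, v.name) for c, v in matched),
        frequency=frequency,
        evidence_level=evidence,
        data_quality="degraded" if degraded else "precise",
        missing_data_notes=tuple(missing),
    )


def generate_plan(
    patient: PatientRecord,
    rulebase: GuidelineRuleBase,
    field_exposure_map: Optional[dict[str, frozenset[str]]] = None,
    as_of: Optional[dt.date] = None,
) -> SurveillancePlan:
    """Evaluate the rule base against a patient and build the PSCP.

    An endpoint enters the plan iff at least one of its conditions evaluates
    TRUE or UNKNOWN — unless it targets an organ whose status is ``removed``,
    in which case it is suppressed with a logged reason.  Pure function of
    (patient, rulebase, exposure map, as_of).
    """
    facts = derive_facts(patient, field_exposure_map, as_of)
    if as_of is None:
        as_of = max(
            line.end_date for diag in patient.diagnoses for line in diag.treatment_lines
        )
    plan = SurveillancePlan(
        patient_id=patient.patient_id,
        generated_at=as_of,
        rulebase_version=rulebase.version,
    )
    for endpoint in rulebase.endpoints:
        item = _build_item(endpoint, facts)
        if item is None:
            continue
        if (
            endpoint.target_organ is not None
            and facts.get("organ_status", endpoint.target_organ) == "removed"
        ):
            plan.suppressed.append(
                {
                    "endpoint_id": endpoint.endpoint_id,
                    "reason": f"target organ {endpoint.target_organ} removed; "
                    "surveillance of this organ is no longer justified",
                }
            )
            continue
        plan.items.append(item)
    return plan


# --------------------------------------------------------------------------
# Physician modifications with audit trail


@dataclass(frozen=True)
class Modification:
    action: str  # deselect | modify_frequency | add_endpoint | accept | annotate
    endpoint_id: str
    frequency: Optional[FrequencySpec] = None
    note: str = ""
    label: str = ""
    kind: str = "specialized_consultation"


def _item_snapshot(item: Optional[PlanItem]) -> Optional[dict]:
    if item is None:
        return None
    d = copy.deepcopy(item.__dict__)
    d["frequency"] = item.frequency.to_dict()
    return d


def apply_modification(
    plan: SurveillancePlan,
    modification: Modification,
    actor: str,
    timestamp: Optional[dt.datetime] = None,
) -> SurveillancePlan:
    """Apply one physician action and append exactly one audit entry.

    Returns a new plan; the input plan is not mutated.  Modifying a
    non-existent item raises KeyError; adding an endpoint already present
    raises ValueError.
    """
    if modification.action not in ("deselect", "modify_frequency", "add_endpoint", "accept", "annotate"):
        raise ValueError(f"unknown action {modification.action!r}")
    new = copy.deepcopy(plan)
    ts = timestamp or dt.datetime.now()

    if modification.action == "add_endpoint":
        if new.has_item(modification.endpoint_id):
            raise ValueError(f"endpoint {modification.endpoint_id!r} already in plan")
        if modification.frequency is None:
            raise ValueError("add_endpoint requires a frequency")
        item = PlanItem(
            endpoint_id=modification.endpoint_id,
            label=modification.label or modification.endpoint_id,
            kind=modification.kind,
            matched_conditions=(),
            frequency=modification.frequency,
            evidence_level="expert_consensus",
            data_quality="precise",
            status="accepted",
            cause="physician_added",
            notes=modification.note,
        )
        before = None
        new.items.append(item)
        after = _item_snapshot(item)
    else:
        target = new.item(modification.endpoint_id)  # KeyError if absent
        before = _item_snapshot(target)
        if modification.action == "deselect":
            target.status = "removed"
        elif modification.action == "accept":
            target.status = "accepted"
        elif modification.action == "modify_frequency":
            if modification.frequency is None:
                raise ValueError("modify_frequency requires a frequency")
            target.frequency = modification.frequency
            target.status = "modified"
        elif modification.action == "annotate":
            target.notes = (target.notes + "\n" + modification.note).strip()
        after = _item_snapshot(target)

    params = {
        "action": modification.action,
        "endpoint_id": modification.endpoint_id,
        "frequency": modification.frequency.to_dict() if modification.frequency else None,
        "note": modification.note,
        "label": modification.label,
        "kind": modification.kind,
    }
    new.audit_log.append(
        AuditEntry(
            timestamp=ts,
            actor=actor,
            action=modification.action,
            endpoint_id=modification.endpoint_id,
            params=params,
            before=before,
            after=after,
        )
    )
    return new


def replay_audit_log(plan: SurveillancePlan, audit_log: list[AuditEntry]) -> SurveillancePlan:
    """Event-sourcing replay: reapply a recorded audit log to a plan."""
    out = copy.deepcopy(plan)
    out.audit_log = []
    for entry in audit_log:
        freq = entry.params.get("frequency")
        mod = Modification(
            action=entry.action,
            endpoint_id=entry.endpoint_id,
            frequency=FrequencySpec.from_dict(freq) if freq else None,
            note=entry.params.get("note", ""),
            label=entry.params.get("label", ""),
            kind=entry.params.get("kind", "specialized_consultation"),
        )
        out = apply_modification(out, mod, entry.actor, entry.timestamp)
    return out


# --------------------------------------------------------------------------
# Serialization / rendering


def plan_to_dict(plan: SurveillancePlan) -> dict:
    return {
        "patient_id": plan.patient_id,
        "generated_at": plan.generated_at.isoformat(),
        "rulebase_version": plan.rulebase_version,
        "items": [_item_snapshot(it) for it in plan.items],
        "suppressed": plan.suppressed,
        "audit_log": [
            {
                "timestamp": e.timestamp.isoformat(),
                "actor": e.actor,
                "action": e.action,
                "endpoint_id": e.endpoint_id,
                "params": e.params,
                "before": e.before,
                "after": e.after,
            }
            for e in plan.audit_log
        ],
    }


def plan_to_json(plan: SurveillancePlan, **kwargs) -> str:
    return json.dumps(plan_to_dict(plan), **kwargs)


def _item_from_dict(d: dict) -> PlanItem:
    d = dict(d)
    d["frequency"] = FrequencySpec.from_dict(d["frequency"])
    d["matched_conditions"] = tuple(tuple(x) for x in d.get("matched_conditions", ()))
    d["missing_data_notes"] = tuple(d.get("missing_data_notes", ()))
    return PlanItem(**d)


def plan_from_dict(doc: dict) -> SurveillancePlan:
    """Inverse of :func:`plan_to_dict`."""
    return SurveillancePlan(
        patient_id=doc["patient_id"],
        generated_at=dt.date.fromisoformat(doc["generated_at"]),
        rulebase_version=doc["rulebase_version"],
        items=[_item_from_dict(d) for d in doc.get("items", ())],
        suppressed=list(doc.get("suppressed", ())),
        audit_log=[
            AuditEntry(
                timestamp=dt.datetime.fromisoformat(e["timestamp"]),
                actor=e["actor"],
                action=e["action"],
                endpoint_id=e["endpoint_id"],
                params=e["params"],
                before=e["before"],
                after=e["after"],
            )
            for e in doc.get("audit_log", ())
        ],
    )


def render_plan_markdown(plan: SurveillancePlan, rulebase: Optional[GuidelineRuleBase] = None) -> str:
    """Human-readable plan with frequency, evidence level and notes per item."""
    lines = [
        f"# Personalized survivorship care plan — patient {plan.patient_id}",
        f"Generated {plan.generated_at.isoformat()} with rule base {plan.rulebase_version}.",
        "",
    ]
    for it in plan.items:
        lines.append(f"## {it.label} ({it.kind.replace('_', ' ')})")
        freq = it.frequency
        every = str(freq.interval)
        until = "lifelong" if freq.end_age is None else f"until age {freq.end_age:g}"
        lines.append(f"- every {every}, anchored on {freq.anchor}, {until}")
        lines.append(f"- evidence level: {it.evidence_level}; status: {it.status}")
        if it.data_quality == "degraded":
            lines.append(
                "- **degraded mode**: precise dosimetric data are missing for "
                + ", ".join(it.missing_data_notes)
            )
        if rulebase is not None:
            try:
                ep = rulebase.endpoint(it.endpoint_id)
            except KeyError:
                ep = None
            if ep is not None:
                if ep.professional_note:
                    lines.append(f"- professional note: {ep.professional_note}")
                if ep.patient_note:
                    lines.append(f"- patient note: {ep.patient_note}")
        if it.notes:
            lines.append(f"- notes: {it.notes}")
        lines.append("")
    if plan.suppressed:
        lines.append("## Suppressed endpoints")
        for s in plan.suppressed:
            lines.append(f"- {s['endpoint_id']}: {s['reason']}")
        lines.append("")
    return "\n".join(lines)
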