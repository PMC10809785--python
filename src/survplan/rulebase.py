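"""Declarative guideline rule base: surveillance endpoints and their conditions.

An endpoint is one follow-up recommendation (a complementary examination, a
specialized consultation, or an educational tool), guarded by 1-34
conditions.  Each condition pairs a predicate over derived patient facts
(organ doses, cumulative agent doses, irradiated fields, predispositions,
organ status, sex, ages, transplant, comorbidities) with a surveillance
frequency, an evidence level and a bibliography.  Predicates are data (YAML
expression trees with AND/OR/NOT nodes), so the rule base can be updated
without touching code.

The packaged default rule base is illustrative — structurally conformant to
published IGHG/PENTEC surveillance topics but NOT a medical product.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Any, Iterator, Optional, Union

import yaml
from dateutil.relativedelta import relativedelta

from . import vocab

EVIDENCE_LEVELS = ("high", "moderate", "low", "very_low", "expert_consensus")
ENDPOINT_KINDS = ("complementary_examination", "specialized_consultation", "educational_tool")
COMPARATORS = ("==", "!=", ">=", "<=", "in")

MAX_CONDITIONS = 34

# fact key -> (value type, argument role or None)
FACT_VOCABULARY: dict[str, tuple[str, Optional[str]]] = {
    "organ_mean_dose": ("numeric", "organ"),
    "field_irradiated": ("bool", "field"),
    "cumulative_dose": ("numeric", "agent"),
    "predisposition": ("bool", "name"),
    "organ_status": ("organ_status", "organ"),
    "sex": ("sex", None),
    "age_at_diagnosis": ("numeric", None),
    "age_at_treatment": ("numeric", None),
    "hsct_received": ("bool", None),
    "hsct_allograft": ("bool", None),
    "comorbidity": ("bool", "code"),
    "supportive_care": ("bool", "kind"),
}

_LEGAL_OPS = {
    "numeric": {"==", "!=", ">=", "<=", "in"},
    "bool": {"==", "!="},
    "organ_status": {"==", "!=", "in"},
    "sex": {"==", "!=", "in"},
}


class RulebaseError(ValueError):
    """Raised when a rule base file violates the structural contract."""


_DURATION_RE = re.compile(r"^P(?:(\d+)Y)?(?:(\d+)M)?(?:(\d+)D)?$")


@dataclass(frozen=True, order=True)
class Duration:
    """ISO-8601 calendar duration restricted to years/months/days (e.g. P2Y)."""

    sort_key: float = field(init=False, repr=False)
    years: int = 0
    months: int = 0
    days: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "sort_key", self.years * 365.25 + self.months * 30.4375 + self.days
        )

    @classmethod
    def parse(cls, text: Union[str, "Duration"]) -> "Duration":
        if isinstance(text, Duration):
            return text
        m = _DURATION_RE.match(str(text))
        if not m or not any(m.groups()):
            raise ValueError(f"invalid ISO-8601 duration {text!r}")
        y, mo, d = (int(g) if g else 0 for g in m.groups())
        return cls(years=y, months=mo, days=d)

    def __str__(self) -> str:
        parts = "".join(
            f"{v}{u}" for v, u in ((self.years, "Y"), (self.months, "M"), (self.days, "D")) if v
        )
        return f"P{parts or '0D'}"

    def as_relativedelta(self) -> relativedelta:
        return relativedelta(years=self.years, months=self.months, days=self.days)

    @property
    def is_zero(self) -> bool:
        return not (self.years or self.months or self.days)


# --------------------------------------------------------------------------
# Predicate expression trees


@dataclass(frozen=True)
class FactAtom:
    fact: str
    op: str
    value: Any
    arg: Optional[str] = None

    @property
    def key(self) -> str:
        return self.fact if self.arg is None else f"{self.fact}({self.arg})"


@dataclass(frozen=True)
class Leaf:
    atom: FactAtom


@dataclass(frozen=True)
class And:
    children: tuple["Predicate", ...]


@dataclass(frozen=True)
class Or:
    children: tuple["Predicate", ...]


@dataclass(frozen=True)
class Not:
    child: "Predicate"


Predicate = Union[Leaf, And, Or, Not]


def parse_predicate(node: Any, path: str = "predicate") -> Predicate:
    """Parse a YAML expression tree into a Predicate.

    Internal nodes: {all: [...]}, {any: [...]}, {not: ...}.  Leaves:
    {fact, op, value, arg?}.
    """
    if not isinstance(node, dict):
        raise RulebaseError(f"{path}: predicate node must be a mapping, got {type(node).__name__}")
    if "all" in node or "any" in node:
        key = "all" if "all" in node else "any"
        children = node[key]
        if not isinstance(children, list) or not children:
            raise RulebaseError(f"{path}.{key}: must be a non-empty list")
        parsed = tuple(parse_predicate(c, f"{path}.{key}[{i}]") for i, c in enumerate(children))
        return And(parsed) if key == "all" else Or(parsed)
    if "not" in node:
        return Not(parse_predicate(node["not"], f"{path}.not"))
    missing = {"fact", "op", "value"} - node.keys()
    if missing:
        raise RulebaseError(f"{path}: leaf missing keys {sorted(missing)}")
    atom = FactAtom(
        fact=str(node["fact"]), op=str(node["op"]), value=node["value"], arg=node.get("arg")
    )
    _check_atom(atom, path)
    return Leaf(atom)


def _check_atom(atom: FactAtom, path: str) -> None:
    if atom.fact not in FACT_VOCABULARY:
        raise RulebaseError(f"{path}: unknown fact key {atom.fact!r}")
    vtype, arg_role = FACT_VOCABULARY[atom.fact]
    if arg_role is None and atom.arg is not None:
        raise RulebaseError(f"{path}: fact {atom.fact!r} takes no argument")
    if arg_role is not None and atom.arg is None:
        raise RulebaseError(f"{path}: fact {atom.fact!r} requires a {arg_role} argument")
    if arg_role == "organ" and atom.arg not in vocab.organs():
        raise RulebaseError(f"{path}: unknown organ code {atom.arg!r}")
    if arg_role == "field" and atom.arg not in vocab.fields():
        raise RulebaseError(f"{path}: unknown field code {atom.arg!r}")
    if arg_role == "agent" and atom.arg not in vocab.agents():
        raise RulebaseError(f"{path}: unknown agent {atom.arg!r}")
    if atom.op not in COMPARATORS:
        raise RulebaseError(f"{path}: unknown comparator {atom.op!r}")
    if atom.op not in _LEGAL_OPS[vtype]:
        raise RulebaseError(f"{path}: comparator {atom.op!r} illegal for {vtype} fact {atom.fact!r}")
    if atom.op == "in" and not isinstance(atom.value, (list, tuple)):
        raise RulebaseError(f"{path}: 'in' comparator requires a list value")


def predicate_to_dict(p: Predicate) -> dict:
    if isinstance(p, Leaf):
        d: dict[str, Any] = {"fact": p.atom.fact, "op": p.atom.op, "value": p.atom.value}
        if p.atom.arg is not None:
            d["arg"] = p.atom.arg
        return d
    if isinstance(p, And):
        return {"all": [predicate_to_dict(c) for c in p.children]}
    if isinstance(p, Or):
        return {"any": [predicate_to_dict(c) for c in p.children]}
    return {"not": predicate_to_dict(p.child)}


def iter_leaves(p: Predicate) -> Iterator[FactAtom]:
    if isinstance(p, Leaf):
        yield p.atom
    elif isinstance(p, (And, Or)):
        for c in p.children:
            yield from iter_leaves(c)
    else:
        yield from iter_leaves(p.child)


# --------------------------------------------------------------------------
# Frequency, condition, endpoint, rule base


@dataclass(frozen=True)
class FrequencySpec:
    """How often and from when an examination recurs.

    ``interval`` > 0; due dates are anchor + start_offset + k * interval.
    ``end_age`` bounds surveillance by patient age (None = lifelong).
    """

    interval: Duration
    anchor: str = "end_of_treatment"
    anchor_age: Optional[float] = None
    start_offset: Duration = Duration()
    end_age: Optional[float] = None

    def __post_init__(self) -> None:
        if self.interval.is_zero:
            raise RulebaseError("frequency interval must be > 0")
        if self.anchor not in ("end_of_treatment", "diagnosis", "fixed_age"):
            raise RulebaseError(f"unknown anchor {self.anchor!r}")
        if (self.anchor == "fixed_age") != (self.anchor_age is not None):
            raise RulebaseError("anchor_age required iff anchor=fixed_age")

    @classmethod
    def from_dict(cls, d: dict) -> "FrequencySpec":
        end = d.get("end", "lifelong")
        return cls(
            interval=Duration.parse(d["interval"]),
            anchor=d.get("anchor", "end_of_treatment"),
            anchor_age=d.get("anchor_age"),
            start_offset=Duration.parse(d.get("start_offset", "P0D")) if d.get("start_offset") else Duration(),
            end_age=None if end in (None, "lifelong") else float(end),
        )

    def to_dict(self) -> dict:
        d: dict[str, Any] = {"interval": str(self.interval), "anchor": self.anchor}
        if self.anchor_age is not None:
            d["anchor_age"] = self.anchor_age
        if not self.start_offset.is_zero:
            d["start_offset"] = str(self.start_offset)
        d["end"] = "lifelong" if self.end_age is None else self.end_age
        return d


@dataclass(frozen=True)
class Condition:
    condition_id: str
    predicate: Predicate
    frequency: FrequencySpec
    evidence_level: str
    bibliography: tuple[str, ...] = ()
    note: str = ""

    def __post_init__(self) -> None:
        if self.evidence_level not in EVIDENCE_LEVELS:
            raise RulebaseError(
                f"condition {self.condition_id}: unknown evidence level {self.evidence_level!r}"
            )


@dataclass(frozen=True)
class Endpoint:
    endpoint_id: str
    label: str
    kind: str
    conditions: tuple[Condition, ...]
    target_organ: Optional[str] = None
    professional_note: str = ""
    patient_note: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ENDPOINT_KINDS:
            raise RulebaseError(f"endpoint {self.endpoint_id}: unknown kind {self.kind!r}")
        if not (1 <= len(self.conditions) <= MAX_CONDITIONS):
            raise RulebaseError(
                f"endpoint {self.endpoint_id}: must have between 1 and {MAX_CONDITIONS} "
                f"conditions, got {len(self.conditions)}"
            )
        if self.target_organ is not None and self.target_organ not in vocab.organs():
            raise RulebaseError(
                f"endpoint {self.endpoint_id}: unknown target organ {self.target_organ!r}"
            )
        if not self.patient_note.strip():
            raise RulebaseError(f"endpoint {self.endpoint_id}: patient_note is required")
        ids = [c.condition_id for c in self.conditions]
        if len(set(ids)) != len(ids):
            raise RulebaseError(f"endpoint {self.endpoint_id}: duplicate condition ids")


@dataclass(frozen=True)
class GuidelineRuleBase:
    version: str
    guideline_sources: tuple[str, ...]
    endpoints: tuple[Endpoint, ...]

    def __post_init__(self) -> None:
        ids = [e.endpoint_id for e in self.endpoints]
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        if dupes:
            raise RulebaseError(f"duplicate endpoint ids: {dupes}")

    def endpoint(self, endpoint_id: str) -> Endpoint:
        for e in self.endpoints:
            if e.endpoint_id == endpoint_id:
                return e
        raise KeyError(endpoint_id)


# --------------------------------------------------------------------------
# Loading / serialization / validation


def _parse_condition(d: dict, path: str) -> Condition:
    for req in ("condition_id", "predicate", "frequency", "evidence_level"):
        if req not in d:
            raise RulebaseError(f"{path}: missing required key {req!r}")
    return Condition(
        condition_id=str(d["condition_id"]),
        predicate=parse_predicate(d["predicate"], f"{path}.predicate"),
        frequency=FrequencySpec.from_dict(d["frequency"]),
        evidence_level=str(d["evidence_level"]),
        bibliography=tuple(d.get("bibliography", ())),
        note=str(d.get("note", "")),
    )


def rulebase_from_dict(doc: dict) -> GuidelineRuleBase:
    if not isinstance(doc, dict):
        raise RulebaseError("rule base document must be a mapping")
    endpoints = []
    for i, ed in enumerate(doc.get("endpoints", ())):
        path = f"endpoints[{i}]({ed.get('endpoint_id', '?')})"
        conditions = tuple(
            _parse_condition(cd, f"{path}.conditions[{j}]")
            for j, cd in enumerate(ed.get("conditions", ()))
        )
        endpoints.append(
            Endpoint(
                endpoint_id=str(ed.get("endpoint_id", "")),
                label=str(ed.get("label", "")),
                kind=str(ed.get("kind", "")),
                target_organ=ed.get("target_organ"),
                conditions=conditions,
                professional_note=str(ed.get("professional_note", "")),
                patient_note=str(ed.get("patient_note", "")),
            )
        )
    return GuidelineRuleBase(
        version=str(doc.get("version", "")),
        guideline_sources=tuple(doc.get("sources", ())),
        endpoints=tuple(endpoints),
    )


def load_rulebase(path: Union[str, Path]) -> GuidelineRuleBase:
    """Load and fully validate a YAML rule base; raise RulebaseError listing
    the first offending element otherwise."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return rulebase_from_dict(doc)


def rulebase_to_dict(rb: GuidelineRuleBase) -> dict:
    return {
        "version": rb.version,
        "sources": list(rb.guideline_sources),
        "endpoints": [
            {
                "endpoint_id": e.endpoint_id,
                "label": e.label,
                "kind": e.kind,
                **({"target_organ": e.target_organ} if e.target_organ else {}),
                "professional_note": e.professional_note,
                "patient_note": e.patient_note,
                "conditions": [
                    {
                        "condition_id": c.condition_id,
                        "predicate": predicate_to_dict(c.predicate),
                        "frequency": c.frequency.to_dict(),
                        "evidence_level": c.evidence_level,
                        "bibliography": list(c.bibliography),
                        **({"note": c.note} if c.note else {}),
                    }
                    for c in e.conditions
                ],
            }
            for e in rb.endpoints
        ],
    }


def rulebase_to_yaml(rb: GuidelineRuleBase) -> str:
    return yaml.safe_dump(rulebase_to_dict(rb), sort_keys=False, allow_unicode=True)


@lru_cache(maxsize=1)
def default_rulebase() -> GuidelineRuleBase:
    """The packaged illustrative rule base (53 endpoints)."""
    text = resources.files("survplan.data").joinpath("rulebase.yaml").read_text()
    return rulebase_from_dict(yaml.safe_load(text))


def _conjunction_contradictions(p: Predicate, path: str) -> list[str]:
    """Detect empty numeric intervals inside AND nodes (e.g. age>=30 & age<=20)."""
    warnings: list[str] = []
    if isinstance(p, And):
        lower: dict[str, float] = {}
        upper: dict[str, float] = {}
        for child in p.children:
            if isinstance(child, Leaf) and child.atom.op in (">=", "<="):
                try:
                    v = float(child.atom.value)
                except (TypeError, ValueError):
                    continue
                k = child.atom.key
                if child.atom.op == ">=":
                    lower[k] = max(lower.get(k, v), v)
                else:
                    upper[k] = min(upper.get(k, v), v)
        for k in lower.keys() & upper.keys():
            if lower[k] > upper[k]:
                warnings.append(
                    f"{path}: contradiction on {k} (>= {lower[k]} and <= {upper[k]} is empty)"
                )
    if isinstance(p, (And, Or)):
        for i, c in enumerate(p.children):
            warnings.extend(_conjunction_contradictions(c, f"{path}[{i}]"))
    elif isinstance(p, Not):
        warnings.extend(_conjunction_contradictions(p.child, f"{path}.not"))
    return warnings


def validate_rulebase(rb: GuidelineRuleBase) -> dict:
    """Report-only structural validation of a loaded rule base.

    Returns {errors, warnings, condition_counts, min_conditions, max_conditions}.
    Contradictory conjunctions (empty numeric intervals) are warnings.
    """
    warnings: list[str] = []
    counts: dict[str, int] = {}
    for e in rb.endpoints:
        counts[e.endpoint_id] = len(e.conditions)
        for c in e.conditions:
            warnings.extend(
                _conjunction_contradictions(c.predicate, f"{e.endpoint_id}/{c.condition_id}")
            )
    return {
        "errors": [],
        "warnings": warnings,
        "condition_counts": counts,
        "min_conditions": min(counts.values()) if counts else 0,
        "max_conditions": max(counts.values()) if counts else 0,
        "n_endpoints": len(rb.endpoints),
    }
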