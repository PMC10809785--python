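"""Synthetic survivor cohorts with the statistical structure of the source
registry's published profile, plus the profiler that recomputes that
profile from any cohort.

The generator draws, per patient: disease category, sex, age at diagnosis
(gamma truncated to the published [0, 23.2] range with its scale solved so
the truncated mean equals the published 8.34 years), first-line treatment
flags honouring the preset marginals (simple monitoring forces all other
modalities off), plausible sub-records for each modality (protocol arms
with theoretical doses, radiotherapy fields with organ dosimetry present in
half the courses so degraded mode is exercised, surgery with functional
impact), transplant, tumor-bank availability, recurrences (whose disease
composition follows the preset weights) and second cancers.  Exactly one
patient per cohort (n >= 2) withholds research consent, mirroring the single
published refusal.  Generation is a pure function of the preset (seed
included).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Optional, Union

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy import stats
from scipy.optimize import brentq

from .model import DiseaseCategory, PatientRecord, validate_patient
from .summary import DoseTable, default_dose_table

DISEASE_CATEGORIES: tuple[str, ...] = (
    "leukemia",
    "cerebral_tumor",
    "lymphoma",
    "sarcoma",
    "kidney_tumor",
    "neuroblastoma",
    "other",
    "rare_tumor",
    "extra_cerebral_germ_cell_tumor",
)

GAMMA_SHAPE = 2.0  # right-skewed age-at-diagnosis family; scale is solved

# plausible protocol arms per disease (keys into the packaged dose table)
_PROTOCOLS: dict[str, tuple[tuple[str, str], ...]] = {
    "leukemia": (("ALL-2020", "standard_risk"), ("ALL-2020", "high_risk"), ("AML-2019", "induction")),
    "cerebral_tumor": (("MB-SIOP", "standard"), ("LGG-VC", "standard")),
    "lymphoma": (("HL-EuroNet", "OEPA"), ("HL-EuroNet", "OEPA_COPDAC"), ("NHL-LMB", "group_B")),
    "sarcoma": (("EWS-2008", "VIDE"), ("OS-2016", "MAP"), ("RMS-EpSSG", "IVA")),
    "kidney_tumor": (("WT-SIOP", "AV"), ("WT-SIOP", "AVD")),
    "neuroblastoma": (("NB-HR", "induction"),),
    "rare_tumor": (("GCT-PEI", "standard"),),
    "extra_cerebral_germ_cell_tumor": (("GCT-PEI", "standard"),),
    "other": (("LGG-VC", "standard"),),
}

_SURGERY_ORGAN: dict[str, str] = {
    "leukemia": "spleen",
    "cerebral_tumor": "brain",
    "lymphoma": "spleen",
    "sarcoma": "bone",
    "kidney_tumor": "kidney",
    "neuroblastoma": "adrenal",
    "rare_tumor": "liver",
    "extra_cerebral_germ_cell_tumor": "ovary",  # testis for boys, handled below
    "other": "bowel",
}

_RT_FIELDS: dict[str, tuple[str, ...]] = {
    "leukemia": ("cranial",),
    "cerebral_tumor": ("cranial", "spinal"),
    "lymphoma": ("supra_diaphragmatic", "cervical", "mediastinal"),
    "sarcoma": ("limb", "pelvic"),
    "kidney_tumor": ("abdominal",),
    "neuroblastoma": ("abdominal",),
    "rare_tumor": ("pelvic", "abdominal"),
    "extra_cerebral_germ_cell_tumor": ("pelvic",),
    "other": ("cervical", "limb"),
}

_PREDISPOSITIONS: tuple[tuple[str, Optional[str]], ...] = (
    ("Li-Fraumeni syndrome", "TP53"),
    ("Neurofibromatosis type 1", "NF1"),
    ("DICER1 syndrome", "DICER1"),
    ("WT1-related syndrome", "WT1"),
    ("Constitutional mismatch repair deficiency", "PMS2"),
)


class PresetError(ValueError):
    pass


class CohortPreset(BaseModel):
    """Parameter bundle driving the synthetic cohort generator."""

    model_config = ConfigDict(extra="forbid")

    name: str = "custom"
    n: int = Field(ge=0)
    seed: int = 1
    disease_probs: dict[str, float]
    sex_prob_male: float = Field(ge=0, le=1)
    age_mean: float = Field(gt=0)
    age_range: tuple[float, float]
    p_surgery: float = Field(ge=0, le=1)
    p_medical_treatment: float = Field(ge=0, le=1)
    p_radiotherapy: float = Field(ge=0, le=1)
    p_rt_and_medical: float = Field(ge=0, le=1)
    p_surgery_only: float = Field(ge=0, le=1)
    p_autotransplant: float = Field(ge=0, le=1)
    p_allograft: float = Field(ge=0, le=1)
    p_simple_monitoring: float = Field(ge=0, le=1)
    p_tumor_bank: float = Field(ge=0, le=1)
    p_recurrence: float = Field(ge=0, le=1)
    p_second_cancer: float = Field(ge=0, le=1)
    p_predisposition: float = Field(default=0.10, ge=0, le=1)
    recurrence_disease_weights: dict[str, float]
    second_cancer_type_weights: dict[str, float]

    @model_validator(mode="after")
    def _consistent(self) -> "CohortPreset":
        unknown = set(self.disease_probs) - set(DISEASE_CATEGORIES)
        if unknown:
            raise PresetError(f"unknown disease categories {sorted(unknown)}")
        total = sum(self.disease_probs.values())
        if total <= 0:
            raise PresetError("disease_probs must have positive mass")
        # normalize (presets may give counts); must land within 1e-9 of 1
        object.__setattr__(
            self,
            "disease_probs",
            {k: v / total for k, v in self.disease_probs.items()},
        )
        if abs(sum(self.disease_probs.values()) - 1.0) > 1e-9:
            raise PresetError("disease_probs must sum to 1")
        if self.p_rt_and_medical > min(self.p_radiotherapy, self.p_medical_treatment) + 1e-12:
            raise PresetError("p_rt_and_medical exceeds min(p_radiotherapy, p_medical_treatment)")
        if self.p_autotransplant + self.p_allograft > self.p_medical_treatment + 1e-12:
            raise PresetError("transplant probabilities exceed p_medical_treatment")
        if self.p_simple_monitoring + self.p_medical_treatment > 1 + 1e-9:
            raise PresetError("p_simple_monitoring incompatible with p_medical_treatment")
        lo, hi = self.age_range
        if not (0 <= lo < hi):
            raise PresetError("age_range must satisfy 0 <= min < max")
        if not (lo < self.age_mean < hi):
            raise PresetError("age_mean must lie inside age_range")
        for weights, label in (
            (self.recurrence_disease_weights, "recurrence_disease_weights"),
            (self.second_cancer_type_weights, "second_cancer_type_weights"),
        ):
            if set(weights) - set(DISEASE_CATEGORIES):
                raise PresetError(f"{label}: unknown disease categories")
            if sum(weights.values()) <= 0:
                raise PresetError(f"{label} must have positive mass")
        return self


def load_preset(source: Union[str, Path, dict]) -> CohortPreset:
    """Load a preset from a name ('table1'), a YAML path, or a mapping."""
    if isinstance(source, dict):
        return CohortPreset.model_validate(source)
    if str(source) == "table1":
        text = resources.files("survplan.data").joinpath("preset_table1.yaml").read_text()
        return CohortPreset.model_validate(yaml.safe_load(text))
    with open(source) as fh:
        return CohortPreset.model_validate(yaml.safe_load(fh))


@lru_cache(maxsize=32)
def _solve_age_scale(age_mean: float, lo: float, hi: float) -> float:
    """Scale of a Gamma(GAMMA_SHAPE, scale) whose mean truncated to
    [lo, hi] equals age_mean."""

    def truncated_mean(scale: float) -> float:
        g = stats.gamma(GAMMA_SHAPE, scale=scale)
        g1 = stats.gamma(GAMMA_SHAPE + 1, scale=scale)
        num = GAMMA_SHAPE * scale * (g1.cdf(hi) - g1.cdf(lo))
        den = g.cdf(hi) - g.cdf(lo)
        return num / den

    return brentq(lambda s: truncated_mean(s) - age_mean, 1e-3, 200.0, xtol=1e-10)


def _sample_ages(rng: np.random.Generator, n: int, preset: CohortPreset) -> np.ndarray:
    lo, hi = preset.age_range
    scale = _solve_age_scale(preset.age_mean, lo, hi)
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.gamma(GAMMA_SHAPE, scale, size=max(16, int((n - filled) * 1.25)))
        keep = draw[(draw >= lo) & (draw <= hi)][: n - filled]
        out[filled : filled + keep.size] = keep
        filled += keep.size
    return out


def _choice(rng: np.random.Generator, weights: dict[str, float]) -> str:
    keys = list(weights)
    p = np.array([weights[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=p / p.sum())]


def _chemo_course(
    protocol: str, arm: str, start: dt.date, end: dt.date, dose_table: DoseTable, conditioning: bool = False
) -> dict:
    return {
        "protocol_id": protocol,
        "arm_id": arm,
        "start_date": start.isoformat(),
        "end_date": end.isoformat(),
        "hsct_conditioning": conditioning,
        "agent_doses": [
            {
                "agent": e.agent,
                "cumulative_dose": e.cumulative_dose,
                "units": e.units,
                "source": "table_default",
            }
            for e in dose_table.lookup(protocol, arm)
        ],
    }


def _rt_course(
    rng: np.random.Generator,
    disease: str,
    start: dt.date,
    exposure_map: dict[str, frozenset[str]],
) -> dict:
    fld = _RT_FIELDS[disease][int(rng.integers(len(_RT_FIELDS[disease])))]
    prescribed = float(np.round(rng.uniform(12.0, 54.0), 1))
    end = start + dt.timedelta(days=int(rng.integers(28, 45)))
    with_dosimetry = bool(rng.random() < 0.5)  # half the courses exercise degraded mode
    organ_doses = []
    if with_dosimetry:
        exposed = sorted(exposure_map.get(fld, frozenset()))
        for organ in exposed:
            if rng.random() < 0.8 or not organ_doses:
                mean = float(np.round(prescribed * rng.uniform(0.02, 1.0), 2))
                organ_doses.append({"organ": organ, "mean_dose": mean})
    return {
        "start_date": start.isoformat(),
        "end_date": end.isoformat(),
        "fields_irradiated": [fld],
        "prescribed_dose": prescribed,
        "dosimetry_available": bool(organ_doses),
        "organ_doses": organ_doses,
    }


def _surgery(rng: np.random.Generator, disease: str, sex: str, date: dt.date) -> dict:
    organ = _SURGERY_ORGAN[disease]
    if disease == "extra_cerebral_germ_cell_tumor" and sex == "male":
        organ = "testis"
    carcinological = ["complete_resection", "microscopically_incomplete", "macroscopically_incomplete"][
        int(rng.choice(3, p=[0.7, 0.2, 0.1]))
    ]
    functional = ["none", "partial_removal", "complete_removal"][int(rng.choice(3, p=[0.55, 0.30, 0.15]))]
    return {
        "date": date.isoformat(),
        "organ": organ,
        "carcinological_impact": carcinological,
        "functional_impact": functional,
    }


def _treatment_line(
    rng: np.random.Generator,
    line_number: int,
    disease: str,
    sex: str,
    start: dt.date,
    flags: dict[str, bool],
    dose_table: DoseTable,
    exposure_map: dict[str, frozenset[str]],
) -> dict:
    duration = int(rng.integers(120, 400))
    end = start + dt.timedelta(days=duration)
    line: dict = {
        "line_number": line_number,
        "start_date": start.isoformat(),
        "end_date": end.isoformat(),
        "surgeries": [],
        "chemo_courses": [],
        "rt_courses": [],
        "hsct": None,
        "supportive_care": [],
    }
    if flags.get("surgery"):
        offset = int(rng.integers(7, max(8, duration // 2)))
        line["surgeries"].append(_surgery(rng, disease, sex, start + dt.timedelta(days=offset)))
    if flags.get("medical"):
        protocols = _PROTOCOLS[disease]
        protocol, arm = protocols[int(rng.integers(len(protocols)))]
        c_end = start + dt.timedelta(days=int(duration * 0.8))
        line["chemo_courses"].append(_chemo_course(protocol, arm, start, c_end, dose_table))
        if rng.random() < 0.4:
            line["supportive_care"].append("corticotherapy")
        if rng.random() < 0.3:
            line["supportive_care"].append("transfusion")
    if flags.get("rt"):
        rt_start = start + dt.timedelta(days=int(rng.integers(30, max(31, duration - 40))))
        line["rt_courses"].append(_rt_course(rng, disease, rt_start, exposure_map))
    if flags.get("hsct"):
        graft = flags["hsct"]
        cond_start = end - dt.timedelta(days=30)
        arm = "bu_mel"
        line["chemo_courses"].append(
            _chemo_course("HSCT-COND", arm, cond_start, cond_start + dt.timedelta(days=8), dose_table, conditioning=True)
        )
        line["hsct"] = {"date": (cond_start + dt.timedelta(days=10)).isoformat(), "graft": graft}
        if rng.random() < 0.3:
            line["supportive_care"].append("fertility_preservation")
    return line


def generate_cohort(
    preset: Union[CohortPreset, str, dict],
    n: Optional[int] = None,
    seed: Optional[int] = None,
) -> list[PatientRecord]:
    """Generate a synthetic cohort of validated patient records.

    ``n`` and ``seed`` override the preset's values.  Fully reproducible:
    the same (preset, n, seed) always yields byte-identical records.
    """
    preset = load_preset(preset) if not isinstance(preset, CohortPreset) else preset
    n = preset.n if n is None else n
    seed = preset.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    dose_table = default_dose_table()
    from .engine import default_exposure_map

    exposure_map = default_exposure_map()

    if n == 0:
        return []

    ages = _sample_ages(rng, n, preset)
    p_not_sm = 1.0 - preset.p_simple_monitoring
    refusal_index = int(rng.integers(n)) if n >= 2 else -1

    patients: list[PatientRecord] = []
    for i in range(n):
        disease = _choice(rng, preset.disease_probs)
        sex = "male" if rng.random() < preset.sex_prob_male else "female"
        age = float(ages[i])
        diag_date = dt.date(2015, 7, 1) + dt.timedelta(days=int(rng.integers(-2700, 2700)))
        birth_date = diag_date - dt.timedelta(days=int(round(age * 365.25)))

        monitoring = rng.random() < preset.p_simple_monitoring
        flags: dict[str, object] = {}
        if not monitoring:
            p_med = min(1.0, preset.p_medical_treatment / p_not_sm)
            medical = rng.random() < p_med
            p_rt_med = preset.p_rt_and_medical / p_not_sm
            p_rt = preset.p_radiotherapy / p_not_sm
            if medical:
                # when every treated patient is medical, the radiotherapy
                # marginal must be hit inside the medical branch
                p_rt_given_med = p_rt if p_med >= 1.0 else min(1.0, p_rt_med / max(p_med, 1e-12))
                rt = rng.random() < min(1.0, p_rt_given_med)
            else:
                residual = max(0.0, p_rt - p_rt_med)
                rt = rng.random() < min(1.0, residual / max(1.0 - p_med, 1e-12))
            surgery = rng.random() < min(1.0, preset.p_surgery / p_not_sm)
            if not (medical or rt or surgery):
                # a treated line needs at least one modality; medical is the
                # overwhelmingly most common fallback
                medical = preset.p_medical_treatment > 0
                surgery = not medical
            hsct: object = False
            if medical:
                u = rng.random()
                p_auto = preset.p_autotransplant / max(preset.p_medical_treatment, 1e-12)
                p_allo = preset.p_allograft / max(preset.p_medical_treatment, 1e-12)
                if u < p_auto:
                    hsct = "autograft"
                elif u < p_auto + p_allo:
                    hsct = "allograft"
            flags = {"surgery": surgery, "medical": medical, "rt": rt, "hsct": hsct}

        line_start = diag_date + dt.timedelta(days=int(rng.integers(7, 28)))
        if monitoring:
            lines = [
                {
                    "line_number": 1,
                    "start_date": line_start.isoformat(),
                    "end_date": line_start.isoformat(),
                    "surgeries": [],
                    "chemo_courses": [],
                    "rt_courses": [],
                    "hsct": None,
                    "supportive_care": [],
                }
            ]
        else:
            lines = [
                _treatment_line(rng, 1, disease, sex, line_start, flags, dose_table, exposure_map)
            ]

        # recurrence: the recurrent subgroup's disease composition follows
        # the preset weights
        w = preset.recurrence_disease_weights
        w_total = sum(w.values())
        p_rec = preset.p_recurrence * (w.get(disease, 0.0) / w_total) / max(
            preset.disease_probs.get(disease, 1e-12), 1e-12
        )
        if rng.random() < min(1.0, p_rec):
            prev_end = dt.date.fromisoformat(lines[-1]["end_date"])
            rec_start = prev_end + dt.timedelta(days=int(rng.integers(180, 1400)))
            lines.append(
                _treatment_line(
                    rng,
                    2,
                    disease,
                    sex,
                    rec_start,
                    {"surgery": False, "medical": True, "rt": False, "hsct": False},
                    dose_table,
                    exposure_map,
                )
            )

        diagnoses = [
            {
                "date": diag_date.isoformat(),
                "disease_category": disease,
                "cancer_rank": 1,
                "tumor_bank_sample": bool(rng.random() < preset.p_tumor_bank),
                "treatment_lines": lines,
            }
        ]

        if rng.random() < preset.p_second_cancer:
            sc_disease = _choice(rng, preset.second_cancer_type_weights)
            last_end = dt.date.fromisoformat(lines[-1]["end_date"])
            sc_date = last_end + dt.timedelta(days=int(rng.integers(900, 5500)))
            sc_start = sc_date + dt.timedelta(days=14)
            diagnoses.append(
                {
                    "date": sc_date.isoformat(),
                    "disease_category": sc_disease,
                    "cancer_rank": 2,
                    "tumor_bank_sample": bool(rng.random() < preset.p_tumor_bank),
                    "treatment_lines": [
                        _treatment_line(
                            rng,
                            1,
                            sc_disease,
                            sex,
                            sc_start,
                            {"surgery": False, "medical": True, "rt": False, "hsct": False},
                            dose_table,
                            exposure_map,
                        )
                    ],
                }
            )

        predispositions = []
        if rng.random() < preset.p_predisposition:
            name, gene = _PREDISPOSITIONS[int(rng.integers(len(_PREDISPOSITIONS)))]
            predispositions.append({"name": name, "gene": gene, "confirmed": bool(rng.random() < 0.8)})

        follow_up_events = []
        if rng.random() < 0.02:
            ev_date = dt.date.fromisoformat(lines[0]["end_date"]) + dt.timedelta(
                days=int(rng.integers(365, 3650))
            )
            follow_up_events.append(
                {
                    "date": ev_date.isoformat(),
                    "organ_category": "endocrine",
                    "event_type": "organ_loss",
                    "organ": "thyroid",
                    "description": "thyroidectomy during follow-up",
                }
            )

        record = {
            "patient_id": f"SYN{i:06d}",
            "sex": sex,
            "birth_date": birth_date.isoformat(),
            "vital_status": "alive" if rng.random() < 0.9034 else "deceased",
            "centers": [f"C{int(rng.integers(1, 12)):02d}"],
            "diagnoses": diagnoses,
            "follow_up_events": follow_up_events,
            "predispositions": predispositions,
            "residence_unit": f"IRIS{int(rng.integers(0, 5000)):04d}",
            "consent_research": i != refusal_index,
        }
        patients.append(validate_patient(record))

    return _enforce_quotas(patients, preset)


def _enforce_quotas(patients: list[PatientRecord], preset: CohortPreset) -> list[PatientRecord]:
    """Guarantee the cohort exercises every engine path: at least one
    degraded-dosimetry patient, one organ-removal patient and one
    predisposition carrier per 1000 patients (minimum one)."""
    n = len(patients)
    if n == 0:
        return patients
    required = max(1, n // 1000)

    def count(pred) -> int:
        return sum(1 for p in patients if pred(p))

    def has_degraded(p: PatientRecord) -> bool:
        return any(
            not rt.dosimetry_available
            for d in p.diagnoses
            for ln in d.treatment_lines
            for rt in ln.rt_courses
        )

    def has_removal(p: PatientRecord) -> bool:
        return any(
            s.functional_impact == "complete_removal"
            for d in p.diagnoses
            for ln in d.treatment_lines
            for s in ln.surgeries
        ) or any(e.event_type == "organ_loss" for e in p.follow_up_events)

    def has_predisposition(p: PatientRecord) -> bool:
        return bool(p.predispositions)

    # degenerate presets (zero probability for a pathway) are honoured:
    # quotas only apply to pathways the preset can produce
    fixes = []
    if preset.p_radiotherapy > 0 and count(has_degraded) < required:
        fixes.append("degraded")
    if preset.p_surgery > 0 and count(has_removal) < required:
        fixes.append("removal")
    if preset.p_predisposition > 0 and count(has_predisposition) < required:
        fixes.append("predisposition")
    for k, fix in enumerate(fixes):
        idx = k % n
        raw = patients[idx].model_dump(mode="json")
        line = raw["diagnoses"][0]["treatment_lines"][0]
        start = line["start_date"]
        if fix == "degraded":
            line["rt_courses"].append(
                {
                    "start_date": start,
                    "end_date": line["end_date"],
                    "fields_irradiated": ["supra_diaphragmatic"],
                    "prescribed_dose": 20.0,
                    "dosimetry_available": False,
                    "organ_doses": [],
                }
            )
        elif fix == "removal":
            line["surgeries"].append(
                {
                    "date": start,
                    "organ": "kidney",
                    "carcinological_impact": "complete_resection",
                    "functional_impact": "complete_removal",
                }
            )
        else:
            raw["predispositions"].append(
                {"name": "Li-Fraumeni syndrome", "gene": "TP53", "confirmed": True}
            )
        patients[idx] = validate_patient(raw)
    return patients


# --------------------------------------------------------------------------
# Profiling


@dataclass(frozen=True)
class CohortProfile:
    """Cohort-level counts and percentages mirroring the published profile."""

    n: int
    disease_counts: dict[str, int]
    disease_pct: dict[str, Optional[float]]
    mean_age: Optional[float]
    age_range: Optional[tuple[float, float]]
    n_male: int
    pct_male: Optional[float]
    n_tumor_bank: int
    pct_tumor_bank: Optional[float]
    first_line: dict[str, int]
    first_line_pct: dict[str, Optional[float]]
    n_recurrence: int
    pct_recurrence: Optional[float]
    n_second_cancer: int
    pct_second_cancer: Optional[float]

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "disease_counts": self.disease_counts,
            "disease_pct": self.disease_pct,
            "mean_age": self.mean_age,
            "age_range": list(self.age_range) if self.age_range else None,
            "n_male": self.n_male,
            "pct_male": self.pct_male,
            "n_tumor_bank": self.n_tumor_bank,
            "pct_tumor_bank": self.pct_tumor_bank,
            "first_line": self.first_line,
            "first_line_pct": self.first_line_pct,
            "n_recurrence": self.n_recurrence,
            "pct_recurrence": self.pct_recurrence,
            "n_second_cancer": self.n_second_cancer,
            "pct_second_cancer": self.pct_second_cancer,
        }


FIRST_LINE_MODALITIES = (
    "surgery",
    "medical_treatment",
    "autotransplant",
    "radiotherapy",
    "allograft",
    "rt_and_medical",
    "simple_monitoring",
)


def cohort_profile(patients: list[PatientRecord]) -> CohortProfile:
    """Exact counting over a cohort; percentages are null when n == 0.

    A patient counts under a first-line modality if any course of that
    modality exists in line 1 of the first diagnosis.
    """
    n = len(patients)

    def pct(count: int) -> Optional[float]:
        return None if n == 0 else 100.0 * count / n

    disease_counts = {d: 0 for d in DISEASE_CATEGORIES}
    first_line = {m: 0 for m in FIRST_LINE_MODALITIES}
    ages = []
    n_male = n_bank = n_rec = n_sc = 0
    for p in patients:
        first = p.first_diagnosis
        disease_counts[first.disease_category] += 1
        ages.append(p.age_at(first.date))
        if p.sex == "male":
            n_male += 1
        if any(d.tumor_bank_sample for d in p.diagnoses):
            n_bank += 1
        line1 = first.treatment_lines[0]
        has_surgery = bool(line1.surgeries)
        has_medical = bool(line1.chemo_courses)
        has_rt = bool(line1.rt_courses)
        if has_surgery:
            first_line["surgery"] += 1
        if has_medical:
            first_line["medical_treatment"] += 1
        if has_rt:
            first_line["radiotherapy"] += 1
        if has_rt and has_medical:
            first_line["rt_and_medical"] += 1
        if line1.hsct is not None:
            if line1.hsct.graft == "autograft":
                first_line["autotransplant"] += 1
            else:
                first_line["allograft"] += 1
        if line1.is_simple_monitoring:
            first_line["simple_monitoring"] += 1
        if any(ln.line_number >= 2 for d in p.diagnoses for ln in d.treatment_lines):
            n_rec += 1
        if any(d.cancer_rank >= 2 for d in p.diagnoses):
            n_sc += 1

    return CohortProfile(
        n=n,
        disease_counts=disease_counts,
        disease_pct={d: pct(c) for d, c in disease_counts.items()},
        mean_age=float(np.mean(ages)) if ages else None,
        age_range=(float(min(ages)), float(max(ages))) if ages else None,
        n_male=n_male,
        pct_male=pct(n_male),
        n_tumor_bank=n_bank,
        pct_tumor_bank=pct(n_bank),
        first_line=first_line,
        first_line_pct={m: pct(c) for m, c in first_line.items()},
        n_recurrence=n_rec,
        pct_recurrence=pct(n_rec),
        n_second_cancer=n_sc,
        pct_second_cancer=pct(n_sc),
    )
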