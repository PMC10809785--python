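# Methods

This note documents the models, semantics and calibration choices behind
`survplan`, what the synthetic cohort does and does not emulate, and the
package's known limitations.

## Patient data model

A `PatientRecord` is a strict, immutable structure (pydantic) covering one
survivor: administrative data, one or more diagnoses ordered by date
(`cancer_rank` is stored explicitly because second cancers may be
registered retrospectively out of order), treatment lines numbered `1..k`
without gaps (line ≥ 2 = recurrence therapy; a line with no surgery,
chemotherapy, radiotherapy or transplant is *simple monitoring*),
follow-up events with optional CTCAE v5 grades, predisposition syndromes,
lifestyle and social data. Inclusion requires age **< 25 years at first
diagnosis**; ages are computed as exact day counts divided by 365.25, which
is deterministic and timezone-free. Organ, radiotherapy-field,
organ-system and agent vocabularies are closed, versioned code lists
(`data/vocabulary.yaml`); unknown codes are rejected, never coerced.
Chemotherapy doses are mg/m² unless the agent's packaged entry declares
mg/kg (busulfan); no unit conversion is ever performed silently.

Organ status at a date is derived, not stored: an organ is `removed` iff a
surgery with functional impact *complete removal* or an *organ-loss*
follow-up event names it on or before that date; partial removal ranks
below removal; unmentioned organs are `intact`. The derivation is monotone
in time.

## Rule base

Endpoints (53 in the packaged file) each carry 1–34 conditions; both
bounds are enforced at load time and the packaged echocardiography
endpoint attains 34 (IGHG-style risk strata: five anthracyclines × dose
strata, combined chemo-radiotherapy strata, radiotherapy-only strata,
comorbidity interactions, transplant conditioning, young age at cardiac
irradiation). Predicates are data — YAML expression trees with `all` /
`any` / `not` nodes over a fixed fact vocabulary — so clinical updates
never require code changes. Evidence levels use a five-value scale
(`high`, `moderate`, `low`, `very_low`, `expert_consensus`), declared in
the rule-base header so an alternative grading system can be swapped in.
Every endpoint carries a professional note and a patient-facing note.

The packaged rule base is assembled from public IGHG/PENTEC surveillance
topics and national-consensus-style additions. It is structurally
faithful and clinically plausible but **illustrative only**; sites are
expected to replace it. Rule-base validation reports empty numeric
intervals inside conjunctions (e.g. `age ≥ 30 AND age ≤ 20`) as
unreachable-predicate warnings.

## Fact derivation and three-valued evaluation

Facts derived per patient: cumulative dose per agent (summed over every
course of every line; agents never given are 0), irradiated fields,
per-organ mean dose, organ status, predispositions, comorbidities,
supportive care, transplant flags, sex, ages at diagnosis and treatment
start. The per-organ dose follows the degraded-mode convention:

* any course **without** dosimetry whose fields may expose the organ
  (packaged field→organ exposure map, editable CSV; total-body
  irradiation exposes every organ) → `UNKNOWN`, even if another course
  recorded a partial dose — the recorded sum would be a lower bound, so
  the conservative verdict wins;
* otherwise, recorded organ doses summed across courses;
* organs in no irradiated field → 0.

Evaluation uses strong Kleene logic (`FALSE < UNKNOWN < TRUE`; AND = min,
OR = max, NOT reflects). A comparison with an `UNKNOWN` operand is
`UNKNOWN`. The evaluator is verified against an independent brute-force
oracle that enumerates every TRUE/FALSE substitution of unknown leaves —
exhaustively, for every packaged predicate with ≤ 4 leaves over all 3^k
assignments of its fact keys.

An endpoint enters the plan iff some condition is `TRUE` or `UNKNOWN`;
`UNKNOWN` means *propose with caveat*, never *omit* — the plan item is
flagged `degraded` and lists the missing fact keys. When several
conditions match with different frequencies or evidence levels, the item
takes the **shortest interval and the strongest evidence** (the most
protective merge; `expert_consensus` ranks below `very_low`). Endpoints
whose target organ is `removed` at generation time are suppressed with a
logged reason; organ-function endpoints that remain relevant after organ
loss (e.g. thyroid-hormone monitoring after thyroidectomy) simply carry no
target organ. Physician actions (deselect, accept, modify frequency, add
endpoint, annotate) return a new plan and append exactly one audit entry
with before/after snapshots; replaying the audit log onto the original
plan reproduces the final state (event sourcing). Whether a deselection
should survive regeneration after new data arrives is deliberately not
decided by the engine: the audit log preserves the action and the caller
can diff regenerated plans against it.

## Scheduling

Due dates are `anchor + start_offset + k·interval` (calendar arithmetic
via `dateutil.relativedelta`) up to a horizon (default 5 years, schedules
being regenerated on demand) or an age bound. Anchors: end of treatment,
diagnosis, or a fixed age. Pauses are half-open intervals with
*shift-then-respace* semantics: a due date inside a pause moves to the
first day after it and later dates respace from there — a missed
examination is delayed, never dropped. Open-ended pauses suspend all later
entries until replaced by a closed pause. A permanent stop cancels every
pending entry and is irreversible on the schedule object; a pause applied
after a stop changes nothing. Notifications go to the patient and the
attending physician; marking is idempotent. Overdue = due date + grace
(default 3 months, configurable) elapsed without the entry being done.
The schedule is a pure function of (plan items, anchors, pauses, stop):
every operation re-materializes entries, carrying done/notified marks by
(endpoint, occurrence index), and serialization round-trips exactly.

## Summaries, dose tables, export

`resolve_cumulative_doses` returns a protocol arm's theoretical cumulative
doses (versioned CSV shipped with the package; sites substitute their own
catalogue) flagged `table_default`, with per-agent adaptations overriding
as `adapted`; adapting an agent absent from the arm warns but includes it.
The treatment summary covers every line (surgery with carcinological and
functional impact, per-agent cumulative doses across lines, radiotherapy
with organ doses or an explicit missing-dosimetry caveat, transplant,
supportive care, recurrences and second cancers) in Markdown and JSON.

Research exports replace patient identifiers with generated 12-character
tokens drawn from a generator seeded by a secret key — tokens carry no
information from the identifier, assignment is injective and stable for a
given key, and re-identification requires the stored map. Birth dates are
exported as year only with ages pre-computed (data-minimization default;
the exclusion list is configuration, not law). Patients without research
consent are excluded and counted in the manifest unless explicitly
overridden.

## EDI quintiles

Within each department, units are ranked by EDI score and cut at the
20/40/60/80 percentiles with min-rank ties and a ceiling cut
(`quintile = ⌈5·rank/n⌉`), so tied scores share the lower quintile, the
assignment is monotone in the score, and with all-distinct scores the
quintile counts differ from n/5 by at most 1. With fewer units than
quintiles the formula still applies (2 units → quintiles 3 and 5).
Missing scores yield `"unknown"`. Geocoding addresses to units is out of
scope; inputs are pre-resolved unit codes.

## Synthetic cohort calibration

The `table1` preset encodes a published registry profile (n = 2558).
Calibration choices:

* **Disease mix** from the published counts normalized by 2558 (the
  printed percentages sum to 99.4% and cannot form a distribution).
* **Age at diagnosis**: Gamma(shape 2) truncated to the published range
  [0, 23.2] y, with the scale solved numerically so the truncated mean is
  exactly 8.34 y. The source gives only mean and range; the gamma family
  is a declared choice reproducing the right skew of pediatric
  age-at-diagnosis distributions. Sampling is by rejection (acceptance
  ≈ 0.97).
* **Treatment marginals**: the published figures are jointly infeasible —
  97.1% medical treatment cannot coexist with 3.8% untreated (simple
  monitoring) patients and 6.7% surgery-only patients, and the published
  count (2228/2558 = 87.1%) contradicts the printed 97.1%. The preset
  keeps the printed headline marginals exactly (surgery 41.5%, medical
  97.1%, radiotherapy 20.5%) and resolves the conflict in the residuals:
  simple monitoring is set to the 2.9% no-medical complement, every
  treated patient receives medical treatment, and the radiotherapy
  marginal is hit inside the medical branch (so "radiotherapy and medical"
  equals the radiotherapy share, 20.5%, rather than the published 18.6%).
  `p_rt_and_medical` and `p_surgery_only` remain preset parameters and
  drive the joint draw whenever a preset leaves them feasible.
* **Transplants** (3.6% autograft, 3.8% allograft) are drawn within the
  medical branch with a bu-mel-style conditioning course; recurrences
  (12.8% of patients) are drawn so the recurrent subgroup's disease
  composition follows the published weights (33.3% cerebral, 23.8%
  leukemia, 15.9% sarcoma, remainder proportional to prevalence); second
  cancers (1.56%) follow the published type distribution, with adult-type
  cancers mapped to the `other` category. Tumor-bank share uses the
  66.54% figure (the same source also prints 57.4%; the text value wins).
  About 10% of patients carry a predisposition syndrome. Exactly one
  patient per cohort (n ≥ 2) withholds research consent, mirroring the
  single published refusal.
* **Engine-path quotas**: at least one missing-dosimetry patient, one
  organ-removal patient and one predisposition carrier per 1000 patients
  (minimum one) are guaranteed, by minimal deterministic edits when the
  random draw misses them — skipped for degenerate presets whose
  probabilities make the pathway impossible. Half of all radiotherapy
  courses carry organ dosimetry so degraded mode is always exercised.

Generation is a single-stream draw from `numpy.random.default_rng(seed)`:
the same (preset, n, seed) yields byte-identical cohorts. Every record
passes full validation.

What the generator does **not** emulate: survival and mortality over time,
treatment-era drift (the registry spans 1967–2022), correlations between
exposures and disease beyond the protocol/field lookup tables, realistic
center effects, or longitudinal follow-up event trajectories. Passing
round-trip tests therefore shows the engine and profiler are correct and
calibrated — not that the generator reproduces real clinical
heterogeneity.

## Problem sizes and numerical notes

The cohort round-trip checks run at n = 2558 (the registry size) with
tolerances of three binomial standard errors (three standard errors of the
mean for age, bounding the age SD by the uniform-range value 23.2/√12);
the law-of-large-numbers test runs at n = 100 000. The scheduler property
suite checks 10 000 random operation sequences against an independent
date-arithmetic oracle. Duration ordering uses mean calendar lengths
(365.25-day years, 30.4375-day months). The gamma-scale solver uses
Brent's method to 1e-10 on the truncated-mean equation.

## Limitations

* The rule base is illustrative; no claim of clinical completeness or
  fidelity to any guideline's wording.
* Pseudonym files are plain JSON; at-rest encryption and key custody are
  the deployment's responsibility.
* No EMR/DICOM/FHIR ingestion, no geocoding, no notification delivery —
  the package consumes pre-extracted structured inputs and emits
  notification objects.
* Calendar export is JSON only.
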