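# survplan

Personalized survivorship care plans (PSCPs) after childhood and
young-adult cancer: a guideline rule engine with missing-data semantics, a
surveillance scheduler, harmonized treatment summaries, pseudonymized
research exports, deprivation-index quintiles, and a calibrated synthetic
cohort generator.

## The problem

Survivors of childhood cancer carry organ-specific late-effect risks that
depend on exactly what they received decades earlier: cumulative
anthracycline dose, which radiotherapy fields were treated and at what
organ-level dose, alkylator exposure, transplant, surgery that removed or
spared an organ, and any underlying cancer predisposition syndrome.
Long-term follow-up guidelines (IGHG for exposure-based surveillance,
PENTEC for pediatric radiotherapy dose–effect) translate those exposures
into surveillance recommendations — but applying them by hand to each
survivor is error-prone, and real records are often incomplete: frequently
only the irradiated field and prescribed dose are known, not the per-organ
dosimetry.

`survplan` is an offline, testable engine for that workflow, aimed at
long-term-follow-up teams, survivorship-informatics developers and
methodologists. The core objects:

* **Rule base** — a versioned YAML catalogue of surveillance *endpoints*
  (examinations, specialized consultations, educational tools), each
  guarded by 1–34 *conditions*. A condition is a predicate over derived
  patient facts plus a frequency, an evidence level and a bibliography.
  The packaged rule base holds 53 illustrative endpoints and is **not a
  medical product**.
* **Three-valued evaluation** — facts can be `TRUE`, `FALSE` or `UNKNOWN`
  (strong Kleene semantics: `x AND y = min(x,y)`, `x OR y = max(x,y)` over
  `FALSE < UNKNOWN < TRUE`). When a radiotherapy course lacks organ
  dosimetry, the mean dose of every organ its fields may expose is
  `UNKNOWN`, **not zero**; an undecidable condition still triggers its
  endpoint, flagged *degraded* with the missing facts listed. Organs
  outside every irradiated field have dose 0. Endpoints targeting a
  surgically removed organ are suppressed with a logged reason.
* **Schedule** — due dates `anchor + offset + k·interval` up to a horizon
  or an age bound; pauses (pregnancy, intercurrent illness, travel) use
  shift-then-respace semantics; a permanent stop cancels all pending
  entries; overdue detection uses a configurable grace period.
* **Synthetic cohort** — `generate_cohort("table1", n, seed)` draws
  patients whose disease mix, age/sex structure, first-line treatment
  marginals, tumor-bank share, recurrences and second cancers match a
  published French childhood-cancer registry profile (n = 2558, mean age
  at diagnosis 8.34 y on [0, 23.2]), so every module is testable without
  real patient data.

## Worked example

Degraded mode on the classic breast-surveillance case — the same chest
(supra-diaphragmatic) irradiation evaluated with and without organ
dosimetry (`python examples/degraded_mode.py`):

```
with dosimetry (breast spared, 0.4 Gy):
  breast imaging proposed? False

without dosimetry (field + prescribed dose only):
  breast imaging proposed? True
  data quality: degraded
  missing facts: organ_mean_dose(breast)
```

With dosimetry the breast dose (0.4 Gy) is below the 10 Gy surveillance
threshold, so no breast imaging is proposed. Without dosimetry the dose is
unknowable, so imaging **is** proposed — with an explicit caveat naming the
missing fact — because absence of evidence of exposure must not be treated
as evidence of absence.

Cohort round trip (`python examples/simulate_and_profile.py`):

```
n = 2558
mean age at diagnosis: 8.29 y (range 0.1-23.1)
boys: 55.0 %  (preset 54.4 %)
tumor-bank sample: 68.6 % (preset 66.54 %)
first-line treatment:
  surgery               40.0 %  (preset 41.5 %)
  medical_treatment     96.6 %  (preset 97.1 %)
  radiotherapy          19.9 %  (preset 20.5 %)
  simple_monitoring      3.4 %  (preset 2.9 %)
disease mix (top 3):
  leukemia              27.2 % (preset 28.3 %)
  ...
```

Each observed percentage is a binomial draw at n = 2558 around its preset
value; all sit within three standard errors of the calibration.

The other scripts in `examples/` walk through plan generation with full
dosimetry, the surveillance calendar (pauses, notifications, overdue,
stop), treatment summaries plus pseudonymized export, and EDI quintiles.

## Command line

A thin CLI wraps the library:

```bash
survplan simulate --preset table1 --n 100 --seed 7 -o cohort/
survplan validate cohort/SYN000000.json
survplan generate-plan --patient cohort/SYN000000.json -o plan.json
survplan schedule --plan plan.json --patient cohort/SYN000000.json -o sched.json
survplan notify --schedule sched.json --window 2024-01-01 2024-12-31
survplan overdue --schedule sched.json --as-of 2025-06-01
survplan summary --patient cohort/SYN000000.json
survplan export --cohort cohort/ --key s3cret -o export/
survplan edi-quintiles scores.csv -o quintiles.csv
survplan profile cohort/
```

## Layout

```
src/survplan/      model.py (patient records), rulebase.py, engine.py (PSCP),
                   planner.py, summary.py, deprivation.py, cohort.py, cli.py
src/survplan/data/ rulebase.yaml, exposure_map.csv, dose_table.csv,
                   vocabulary.yaml, preset_table1.yaml
docs/methods.md    models, calibration choices, limitations
examples/          one narrative script per capability
tests/             pytest suite (unit, property-based, end-to-end)
```
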