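"""Simulate a survivor cohort and recover its profile.

The 'table1' preset encodes the published registry profile (disease mix,
age and sex structure, first-line treatment marginals, tumor-bank share).
Generating a cohort and profiling it closes the loop: the percentages below
should sit within binomial noise of the preset values.
"""

from survplan import cohort_profile, generate_cohort, load_preset

preset = load_preset("table1")
cohort = generate_cohort(preset, n=2558, seed=1)
profile = cohort_profile(cohort)

print(f"n = {profile.n}")
print(f"mean age at diagnosis: {profile.mean_age:.2f} y "
      f"(range {profile.age_range[0]:.1f}-{profile.age_range[1]:.1f})")
print(f"boys: {profile.pct_male:.1f} %  (preset {100 * preset.sex_prob_male:.1f} %)")
print(f"tumor-bank sample: {profile.pct_tumor_bank:.1f} % "
      f"(preset {100 * preset.p_tumor_bank:.2f} %)")
print("first-line treatment:")
for key, target in [("surgery", preset.p_surgery),
                    ("medical_treatment", preset.p_medical_treatment),
                    ("radiotherapy", preset.p_radiotherapy),
                    ("simple_monitoring", preset.p_simple_monitoring)]:
    print(f"  {key:20s} {profile.first_line_pct[key]:5.1f} %  (preset {100 * target:.1f} %)")
print("disease mix (top 3):")
for disease in ("leukemia", "cerebral_tumor", "lymphoma"):
    print(f"  {disease:20s} {profile.disease_pct[disease]:5.1f} % "
          f"(preset {100 * preset.disease_probs[disease]:.1f} %)")
print(f"patients with recurrence lines: {profile.pct_recurrence:.1f} %")
print(f"patients with a second cancer:  {profile.pct_second_cancer:.1f} %")

# Every generated record passes full validation, so the cohort can feed the
# rule engine, planner and export modules directly.
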