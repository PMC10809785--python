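# Closed, versioned code lists used across the package.
# Unknown codes are rejected at validation time, never coerced.
version: "2024.1"

organs:
  - breast
  - heart
  - lung
  - thyroid
  - salivary_glands
  - carotid
  - brain
  - pituitary
  - lens
  - cochlea
  - kidney
  - bladder
  - liver
  - spleen
  - pancreas
  - bowel
  - ovary
  - uterus
  - testis
  - bone
  - spine
  - skin
  - teeth
  - eye
  - adrenal

# Anatomical radiotherapy field codes; each maps to a set of potentially
# exposed organs in exposure_map.csv (total_body covers every organ).
fields:
  - cranial
  - cervical
  - supra_diaphragmatic
  - mediastinal
  - spinal
  - abdominal
  - pelvic
  - limb
  - total_body

# Organ-system categories used for follow-up events.
organ_systems:
  - cardiovascular
  - respiratory
  - endocrine
  - renal_urinary
  - hepatic_digestive
  - neurologic
  - musculoskeletal
  - dermatologic
  - sensory
  - reproductive
  - hematologic
  - psychosocial
  - other

# Chemotherapy agents recognized by the dose accounting; unit defaults to
# mg/m2 unless listed under mg_per_kg_agents.
agents:
  - doxorubicin
  - daunorubicin
  - epirubicin
  - idarubicin
  - mitoxantrone
  - cyclophosphamide
  - ifosfamide
  - melphalan
  - busulfan
  - procarbazine
  - lomustine
  - carmustine
  - thiotepa
  - cisplatin
  - carboplatin
  - etoposide
  - bleomycin
  - methotrexate
  - cytarabine
  - vincristine
  - vinblastine
  - dactinomycin
  - asparaginase
  - mercaptopurine
  - rituximab
  - imatinib

mg_per_kg_agents:
  - busulfan
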