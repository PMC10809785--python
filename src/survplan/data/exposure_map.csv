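field,organ
cranial,brain
cranial,pituitary
cranial,lens
cranial,cochlea
cranial,eye
cervical,thyroid
cervical,salivary_glands
cervical,carotid
supra_diaphragmatic,breast
supra_diaphragmatic,heart
supra_diaphragmatic,lung
supra_diaphragmatic,thyroid
mediastinal,heart
mediastinal,lung
mediastinal,breast
spinal,spine
spinal,thyroid
spinal,heart
abdominal,kidney
abdominal,liver
abdominal,bowel
abdominal,ovary
abdominal,uterus
abdominal,spleen
abdominal,pancreas
abdominal,adrenal
pelvic,bladder
pelvic,bowel
pelvic,ovary
pelvic,uterus
pelvic,testis
pelvic,bone
limb,bone
limb,skin
total_body,*
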