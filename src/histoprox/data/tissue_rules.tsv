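bstpath	bone_soft_tissue	0
bone	bone_soft_tissue	1
cartilage	bone_soft_tissue	1
soft tissue	bone_soft_tissue	0
osteoid	bone_soft_tissue	1
breastpath	breast	0
breast	breast	1
mammary	breast	1
ductal	breast	1
lobular	breast	1
dermpath	dermatological	0
skin	dermatological	1
cutaneous	dermatological	1
epidermis	dermatological	1
melanocytic	dermatological	1
gipath	gastrointestinal	0
gastric	gastrointestinal	1
colon	gastrointestinal	1
colonic	gastrointestinal	1
esophageal	gastrointestinal	1
intestinal	gastrointestinal	1
stomach	gastrointestinal	1
hepatic	gastrointestinal	1
gupath	genitourinary	0
bladder	genitourinary	1
prostate	genitourinary	1
renal	genitourinary	1
kidney	genitourinary	1
testicular	genitourinary	1
gynpath	gynecological	0
ovarian	gynecological	1
ovary	gynecological	1
uterine	gynecological	1
cervical	gynecological	1
endometrial	gynecological	1
fallopian	gynecological	1
headneckpath	head_neck	0
thyroid	head_neck	1
salivary	head_neck	1
laryngeal	head_neck	1
oral	head_neck	1
tonsil	head_neck	1
hemepath	hematological	0
bone marrow	hematological	0
lymph node	hematological	0
marrow	hematological	1
spleen	hematological	1
neuropath	neurological	0
brain	neurological	1
glial	neurological	1
meninges	neurological	1
spinal	neurological	1
pulmpath	pulmonary	0
lung	pulmonary	1
bronchial	pulmonary	1
pleura	pulmonary	1
alveolar	pulmonary	1
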