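carcinoma in situ	low_grade	0
granulation tissue	nontumor	0
reactive changes	nontumor	0
low grade	low_grade	0
low-grade	low_grade	0
high grade	malignant	0
high-grade	malignant	0
in situ	low_grade	0
carcinoma	malignant	1
adenocarcinoma	malignant	1
sarcoma	malignant	1
lymphoma	malignant	1
melanoma	malignant	1
malignant	malignant	1
malignancy	malignant	1
metastasis	malignant	1
metastatic	malignant	1
cancer	malignant	1
leukemia	malignant	1
adenoma	low_grade	1
benign	low_grade	1
hyperplasia	low_grade	1
hyperplastic	low_grade	1
dysplasia	low_grade	1
preneoplastic	low_grade	1
papilloma	low_grade	1
normal	nontumor	1
artifact	nontumor	1
infection	nontumor	1
inflammation	nontumor	1
inflammatory	nontumor	1
granuloma	nontumor	1
injury	nontumor	1
nontumor	nontumor	1
abscess	nontumor	1
edema	nontumor	1
necrosis	nontumor	1
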