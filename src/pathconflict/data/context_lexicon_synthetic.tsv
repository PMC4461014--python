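term	context_type
liver	OG
lung	OG
brain	OG
kidney	OG
heart	OG
pancreas	OG
stomach	OG
small intestine	OG
spleen	OG
skin	OG
hepatocyte	CT
neutrophil	CT
t-cell	CT
b-cell	CT
fibroblast	CT
macrophage	CT
epithelial cell	CT
neuron	CT
adipocyte	CT
keratinocyte	CT
asthma	DS
acromegaly	DS
schizophrenia	DS
cerebral ischemia	DS
lung adenocarcinoma	DS
type 2 diabetes	DS
breast cancer	DS
stomach cancer	DS
hypertension	DS
arthritis	DS
aspirin	DR
herceptin	DR
metformin	DR
tamoxifen	DR
ibuprofen	DR
warfarin	DR
statin	DR
insulin	DR
cisplatin	DR
rapamycin	DR
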