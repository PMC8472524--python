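# Gene-level therapy associations for the 25-gene panel (TP53 omitted: prognosis only, no drug)
gene	match_kind	protein_change	drug	effect	evidence_tier	tumor_types
AKT1	gene_level		AZD-5363	responsive	clinical_guidelines	breast cancer;ovarian cancer
ALK	gene_level		Crizotinib	responsive	fda_guidelines	non-small cell lung cancer
ARID1A	gene_level		Everolimus	responsive	late_trials	ovarian clear cell cancer
BRAF	gene_level		Vemurafenib	responsive	fda_guidelines	melanoma;colorectal cancer
BRCA1	gene_level		Olaparib	responsive	fda_guidelines	ovarian cancer;breast cancer
BRCA2	gene_level		Olaparib	responsive	fda_guidelines	ovarian cancer;breast cancer
CDK4	gene_level		Palbociclib	responsive	clinical_guidelines	liposarcoma
EGFR	gene_level		Erlotinib	responsive	fda_guidelines	non-small cell lung cancer
ERBB2	gene_level		Trastuzumab	responsive	fda_guidelines	breast cancer;gastric adenocarcinoma
ESR1	gene_level		Fulvestrant	responsive	clinical_guidelines	breast cancer
IDH2	gene_level		Enasidenib	responsive	fda_guidelines	acute myeloid leukemia
KIT	gene_level		Imatinib	responsive	fda_guidelines	gastrointestinal stromal tumor
KRAS	gene_level		Cetuximab	resistant	fda_guidelines	colorectal cancer
KRAS	gene_level		Panitumumab	resistant	fda_guidelines	colorectal cancer
MET	gene_level		Crizotinib	responsive	fda_guidelines	non-small cell lung cancer
MTOR	gene_level		Everolimus	responsive	clinical_guidelines	renal cell carcinoma
NRAS	gene_level		Cetuximab	resistant	fda_guidelines	colorectal cancer
PDGFRA	gene_level		Imatinib	responsive	fda_guidelines	gastrointestinal stromal tumor
PIK3CA	gene_level		Alpelisib	responsive	fda_guidelines	breast cancer
PTCH1	gene_level		Vismodegib	responsive	fda_guidelines	skin basal cell carcinoma
PTEN	gene_level		Everolimus	responsive	clinical_guidelines	renal cell carcinoma
ROS1	gene_level		Crizotinib	responsive	late_trials	non-small cell lung cancer
SMO	gene_level		Vismodegib	responsive	clinical_guidelines	skin basal cell carcinoma
TSC1	gene_level		Everolimus	responsive	fda_guidelines	renal angiomyolipoma
TSC2	gene_level		Everolimus	responsive	fda_guidelines	renal angiomyolipoma
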