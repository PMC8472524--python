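# Exact-match biomarker mutations supported by FDA/professional guidelines
gene	match_kind	protein_change	drug	effect	evidence_tier	tumor_types
BRCA1	exact_protein_change	E1609*	Rucaparib	responsive	fda_guidelines	
BRCA1	exact_protein_change	E1609*	Olaparib	responsive	fda_guidelines	
BRCA1	exact_protein_change	L702Wfs*5	Rucaparib	responsive	fda_guidelines	
BRCA1	exact_protein_change	L702Wfs*5	Olaparib	responsive	fda_guidelines	
BRCA1	exact_protein_change	N1745Tfs*20	Rucaparib	responsive	fda_guidelines	
BRCA1	exact_protein_change	N1745Tfs*20	Olaparib	responsive	fda_guidelines	
BRCA1	exact_protein_change	Q1273*	Rucaparib	responsive	fda_guidelines	
BRCA1	exact_protein_change	Q1273*	Olaparib	responsive	fda_guidelines	
BRCA1	exact_protein_change	V370I	Rucaparib	responsive	fda_guidelines	
BRCA1	exact_protein_change	V370I	Olaparib	responsive	fda_guidelines	
BRCA2	exact_protein_change	A2603S	Rucaparib	responsive	fda_guidelines	
BRCA2	exact_protein_change	A2603S	Olaparib	responsive	fda_guidelines	
BRCA2	exact_protein_change	D1796Mfs*9	Rucaparib	responsive	fda_guidelines	
BRCA2	exact_protein_change	D1796Mfs*9	Olaparib	responsive	fda_guidelines	
BRCA2	exact_protein_change	K3327Nfs*13	Rucaparib	responsive	fda_guidelines	
BRCA2	exact_protein_change	K3327Nfs*13	Olaparib	responsive	fda_guidelines	
BRCA2	exact_protein_change	L1114V	Rucaparib	responsive	fda_guidelines	
BRCA2	exact_protein_change	L1114V	Olaparib	responsive	fda_guidelines	
BRCA2	exact_protein_change	splice_acceptor_variant	Rucaparib	responsive	fda_guidelines	
BRCA2	exact_protein_change	splice_acceptor_variant	Olaparib	responsive	fda_guidelines	
BRCA2	exact_protein_change	T2783Afs*13	Rucaparib	responsive	fda_guidelines	
BRCA2	exact_protein_change	T2783Afs*13	Olaparib	responsive	fda_guidelines	
BRCA2	exact_protein_change	T2790I	Rucaparib	responsive	fda_guidelines	
BRCA2	exact_protein_change	T2790I	Olaparib	responsive	fda_guidelines	
BRCA2	exact_protein_change	I1364M	Rucaparib	responsive	fda_guidelines	
BRCA2	exact_protein_change	I1364M	Olaparib	responsive	fda_guidelines	
BRCA2	exact_protein_change	L398P	Rucaparib	responsive	fda_guidelines	
BRCA2	exact_protein_change	L398P	Olaparib	responsive	fda_guidelines	
BRCA2	exact_protein_change	D635G	Rucaparib	responsive	fda_guidelines	
BRCA2	exact_protein_change	D635G	Olaparib	responsive	fda_guidelines	
BRCA2	exact_protein_change	R2034C	Rucaparib	responsive	fda_guidelines	
BRCA2	exact_protein_change	R2034C	Olaparib	responsive	fda_guidelines	
KRAS	exact_protein_change	A146V	Panitumumab	resistant	fda_guidelines	
KRAS	exact_protein_change	A146V	Cetuximab	resistant	fda_guidelines	
KRAS	exact_protein_change	Q61H	Panitumumab	resistant	fda_guidelines	
KRAS	exact_protein_change	Q61H	Cetuximab	resistant	fda_guidelines	
KRAS	exact_protein_change	G12A	Panitumumab	resistant	fda_guidelines	
KRAS	exact_protein_change	G12A	Cetuximab	resistant	fda_guidelines	
KRAS	exact_protein_change	G12D	Panitumumab	resistant	fda_guidelines	
KRAS	exact_protein_change	G12D	Cetuximab	resistant	fda_guidelines	
KRAS	exact_protein_change	G12V	Panitumumab	resistant	fda_guidelines	
KRAS	exact_protein_change	G12V	Cetuximab	resistant	fda_guidelines	
KRAS	exact_protein_change	L19F	Panitumumab	resistant	fda_guidelines	
KRAS	exact_protein_change	L19F	Cetuximab	resistant	fda_guidelines	
KRAS	exact_protein_change	Q25*fs*1	Panitumumab	resistant	fda_guidelines	
KRAS	exact_protein_change	Q25*fs*1	Cetuximab	resistant	fda_guidelines	
NRAS	exact_protein_change	G12C	Panitumumab	resistant	fda_guidelines	
NRAS	exact_protein_change	G12C	Cetuximab	resistant	fda_guidelines	
NRAS	exact_protein_change	Q61R	Panitumumab	resistant	fda_guidelines	
NRAS	exact_protein_change	Q61R	Cetuximab	resistant	fda_guidelines	
PIK3CA	exact_protein_change	H1047R	Alpelisib+Fulvestrant	responsive	fda_guidelines	
PIK3CA	exact_protein_change	E545A	Alpelisib+Fulvestrant	responsive	fda_guidelines	
PIK3CA	exact_protein_change	E545K	Alpelisib+Fulvestrant	responsive	fda_guidelines	
PIK3CA	exact_protein_change	E542K	Alpelisib+Fulvestrant	responsive	fda_guidelines	
PIK3CA	exact_protein_change	R88Q	Alpelisib+Fulvestrant	responsive	fda_guidelines	
PIK3CA	exact_protein_change	N345S	Alpelisib+Fulvestrant	responsive	fda_guidelines	
PIK3CA	exact_protein_change	E579K	Alpelisib+Fulvestrant	responsive	fda_guidelines	
PTCH1	exact_protein_change	R441H	Vismodegib	responsive	fda_guidelines	
PTCH1	exact_protein_change	D717N	Vismodegib	responsive	fda_guidelines	
PTCH1	exact_protein_change	H1240R	Vismodegib	responsive	fda_guidelines	
PTCH1	exact_protein_change	P725S	Vismodegib	responsive	fda_guidelines	
PTCH1	exact_protein_change	V580A	Vismodegib	responsive	fda_guidelines	
PTCH1	exact_protein_change	T677A	Vismodegib	responsive	fda_guidelines	
PTCH1	exact_protein_change	N871D	Vismodegib	responsive	fda_guidelines	
TSC1	exact_protein_change	K375Sfs*30	Everolimus	responsive	fda_guidelines	
TSC1	exact_protein_change	L826Q	Everolimus	responsive	fda_guidelines	
TSC1	exact_protein_change	L827Q	Everolimus	responsive	fda_guidelines	
TSC1	exact_protein_change	T582S	Everolimus	responsive	fda_guidelines	
TSC2	exact_protein_change	R1729C	Everolimus	responsive	fda_guidelines	
TSC2	exact_protein_change	S1530L	Everolimus	responsive	fda_guidelines	
TSC2	exact_protein_change	K533delK	Everolimus	responsive	fda_guidelines	
TSC2	exact_protein_change	A460T	Everolimus	responsive	fda_guidelines	
TSC2	exact_protein_change	A950T	Everolimus	responsive	fda_guidelines	
TSC2	exact_protein_change	D1084G	Everolimus	responsive	fda_guidelines	
TSC2	exact_protein_change	P1771L	Everolimus	responsive	fda_guidelines	
TSC2	exact_protein_change	S1096C	Everolimus	responsive	fda_guidelines	
TSC2	exact_protein_change	T154I	Everolimus	responsive	fda_guidelines	
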