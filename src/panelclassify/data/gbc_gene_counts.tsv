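# Somatic mutation counts per gene in the 31 gallbladder-cancer samples
gene	n_mutations
TP53	16
KRAS	4
ARID1A	3
ERBB2	2
TSC2	2
PIK3CA	2
PTCH1	2
TSC1	2
BRCA1	1
PTEN	1
BRAF	1
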