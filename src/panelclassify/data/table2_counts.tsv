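# Per-category variant counts from the 131 quality-passed tumor samples
category	total	unique
germline	55	26
putative_germline	0	0
putative_novel_germline	4	3
somatic	125	86
putative_somatic	13	13
putative_novel_somatic	59	45
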