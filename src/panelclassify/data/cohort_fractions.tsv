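# Reported cohort fractions (numerator/denominator pairs)
metric	numerator	denominator
ff_pass	15	19
ffpe_pass	116	164
blood_pass	79	89
samples_with_somatic	111	131
somatic_with_biomarker	137	197
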