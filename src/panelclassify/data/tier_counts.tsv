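# Biomarker evidence-tier hit counts across the clinical cohort
evidence_tier	n_hits
fda_guidelines	44
clinical_guidelines	9
late_trials	37
early_trials	119
case_report	42
pre_clinical	113
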