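factors,probability
hypertension,0.0214
atrial_fibrillation,0.0206
smoking,0.0061
dyslipidemia,0.0084
diabetes,0.016
lack_of_exercise,0.0127
overweight,0.012
family_history,0.0116
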