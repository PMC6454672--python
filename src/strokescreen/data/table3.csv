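factors,probability
dyslipidemia;lack_of_exercise,0.0348
atrial_fibrillation;lack_of_exercise,0.0322
dyslipidemia;diabetes,0.0307
overweight;family_history,0.0291
hypertension;overweight,0.0246
hypertension;dyslipidemia,0.0224
hypertension;smoking,0.0202
smoking;diabetes,0.02
hypertension;diabetes,0.0197
atrial_fibrillation;overweight,0.0179
hypertension;family_history,0.0164
dyslipidemia;family_history,0.0156
diabetes;overweight,0.0134
smoking;overweight,0.0117
dyslipidemia;overweight,0.0112
diabetes;lack_of_exercise,0.0105
hypertension;lack_of_exercise,0.0094
lack_of_exercise;overweight,0.0089
smoking;family_history,0.0082
smoking;lack_of_exercise,0.0079
smoking;dyslipidemia,0.006
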