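factors,probability
atrial_fibrillation;dyslipidemia;family_history,0.2
smoking;diabetes;family_history,0.2
atrial_fibrillation;dyslipidemia;lack_of_exercise,0.1111
hypertension;atrial_fibrillation;family_history,0.1111
atrial_fibrillation;dyslipidemia;overweight,0.0909
smoking;diabetes;lack_of_exercise,0.0909
smoking;dyslipidemia;diabetes,0.0869
hypertension;diabetes;family_history,0.0865
dyslipidemia;diabetes;family_history,0.0833
hypertension;atrial_fibrillation;dyslipidemia,0.0741
hypertension;diabetes;overweight,0.0572
dyslipidemia;overweight;family_history,0.0556
hypertension;smoking;dyslipidemia,0.0531
smoking;dyslipidemia;overweight,0.05
hypertension;dyslipidemia;lack_of_exercise,0.0459
dyslipidemia;lack_of_exercise;family_history,0.0434
smoking;dyslipidemia;family_history,0.0417
hypertension;atrial_fibrillation;lack_of_exercise,0.04
dyslipidemia;diabetes;overweight,0.04
hypertension;lack_of_exercise;family_history,0.0389
hypertension;dyslipidemia;overweight,0.0362
dyslipidemia;diabetes;lack_of_exercise,0.0313
hypertension;lack_of_exercise;overweight,0.0286
hypertension;diabetes;lack_of_exercise,0.0286
hypertension;smoking;overweight,0.0255
dyslipidemia;lack_of_exercise;overweight,0.0244
hypertension;overweight;family_history,0.0236
hypertension;dyslipidemia;diabetes,0.0226
smoking;dyslipidemia;lack_of_exercise,0.0209
hypertension;smoking;family_history,0.0179
hypertension;smoking;lack_of_exercise,0.0178
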