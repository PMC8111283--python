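Grid calibration of synthetic study defaults (failure probabilities and
Gompertz mortality parameters) against the published qualitative
cost-effectiveness pattern; closest (cost, DALY) match wins.

grid points evaluated: 342
candidate {'metformin_only': 0.08, 'metformin_glibenclamide': 0.04, 'metformin_saxagliptin': 0.01} bg=(0.005, 0.07) tx=(0.02, 0.05) score=1.15254
candidate {'metformin_only': 0.08, 'metformin_glibenclamide': 0.04, 'metformin_saxagliptin': 0.01} bg=(0.005, 0.07) tx=(0.05, 0.05) score=0.38606
candidate {'metformin_only': 0.08, 'metformin_glibenclamide': 0.04, 'metformin_saxagliptin': 0.01} bg=(0.01, 0.07) tx=(0.05, 0.05) score=0.14242
candidate {'metformin_only': 0.08, 'metformin_glibenclamide': 0.04, 'metformin_saxagliptin': 0.01} bg=(0.01, 0.07) tx=(0.08, 0.05) score=0.07818
candidate {'metformin_only': 0.08, 'metformin_glibenclamide': 0.04, 'metformin_saxagliptin': 0.01} bg=(0.015, 0.07) tx=(0.05, 0.05) score=0.03660
candidate {'metformin_only': 0.08, 'metformin_glibenclamide': 0.04, 'metformin_saxagliptin': 0.01} bg=(0.015, 0.07) tx=(0.08, 0.05) score=0.03002
candidate {'metformin_only': 0.08, 'metformin_glibenclamide': 0.04, 'metformin_saxagliptin': 0.02} bg=(0.015, 0.07) tx=(0.05, 0.05) score=0.02411
candidate {'metformin_only': 0.08, 'metformin_glibenclamide': 0.04, 'metformin_saxagliptin': 0.02} bg=(0.015, 0.07) tx=(0.08, 0.05) score=0.01898
candidate {'metformin_only': 0.08, 'metformin_glibenclamide': 0.06, 'metformin_saxagliptin': 0.04} bg=(0.015, 0.07) tx=(0.08, 0.05) score=0.01838
candidate {'metformin_only': 0.12, 'metformin_glibenclamide': 0.04, 'metformin_saxagliptin': 0.02} bg=(0.015, 0.07) tx=(0.08, 0.05) score=0.01521
candidate {'metformin_only': 0.12, 'metformin_glibenclamide': 0.06, 'metformin_saxagliptin': 0.04} bg=(0.015, 0.07) tx=(0.08, 0.05) score=0.01461
candidate {'metformin_only': 0.16, 'metformin_glibenclamide': 0.04, 'metformin_saxagliptin': 0.02} bg=(0.015, 0.07) tx=(0.08, 0.05) score=0.01333
candidate {'metformin_only': 0.16, 'metformin_glibenclamide': 0.06, 'metformin_saxagliptin': 0.04} bg=(0.015, 0.07) tx=(0.08, 0.05) score=0.01272
candidate {'metformin_only': 0.2, 'metformin_glibenclamide': 0.04, 'metformin_saxagliptin': 0.02} bg=(0.015, 0.07) tx=(0.08, 0.05) score=0.01245
candidate {'metformin_only': 0.2, 'metformin_glibenclamide': 0.06, 'metformin_saxagliptin': 0.04} bg=(0.015, 0.07) tx=(0.08, 0.05) score=0.01185
points satisfying pattern: 258
selected: StudyDefaults(failure_probabilities={'metformin_only': 0.2, 'metformin_glibenclamide': 0.06, 'metformin_saxagliptin': 0.04}, gompertz_background=(0.015, 0.07), t2dm_excess=(0.08, 0.05))
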