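# 46 chronic diagnosis groups for the elderly multimorbidity pipeline.
#
# The ICD-10 prefix lists are REPRESENTATIVE (synthetic stand-ins for the
# unpublished full grouping): they cover the canonical codes of each group and
# are guaranteed non-overlapping, which is all the pipeline requires.
# prevalence_female / prevalence_male are the synthetic generator's default
# marginal prevalences in the multimorbid 65+ cohort; for the 35 groups that
# appear in the published centrality table they equal the printed
# gender-specific prevalences, for the remaining 11 groups they are invented
# nominal values (marked `synthetic_prevalence: true`).
groups:
  - {id: chronic_low_back_pain, label: "Chronic low back pain", icd10: [M40, M42, M47, M51, M53, M54], restriction: both, prevalence_female: 0.471, prevalence_male: 0.410}
  - {id: joint_arthrosis, label: "Joint arthrosis", icd10: [M15, M16, M17, M19], restriction: both, prevalence_female: 0.336, prevalence_male: 0.248}
  - {id: lower_limb_varicosis, label: "Lower limb varicosis", icd10: [I83], restriction: both, prevalence_female: 0.227, prevalence_male: 0.115}
  - {id: prostatic_hyperplasia, label: "Prostatic hyperplasia", icd10: [N40], restriction: male_only, prevalence_female: 0.0, prevalence_male: 0.281}
  - {id: asthma_copd, label: "Asthma/COPD", icd10: [J44, J45], restriction: both, prevalence_female: 0.141, prevalence_male: 0.163}
  - {id: depression, label: "Depression", icd10: [F32, F33], restriction: both, prevalence_female: 0.181, prevalence_male: 0.078}
  - {id: chronic_gastritis_gerd, label: "Chronic gastritis/GERD", icd10: [K21, K29], restriction: both, prevalence_female: 0.108, prevalence_male: 0.108}
  - {id: osteoporosis, label: "Osteoporosis", icd10: [M80, M81], restriction: both, prevalence_female: 0.197, prevalence_male: 0.036}
  - {id: gynaecological_problems, label: "Gynaecological problems", icd10: [N81, N95], restriction: female_only, prevalence_female: 0.166, prevalence_male: 0.0}
  - {id: allergies, label: "Allergies", icd10: [J30, L23], restriction: both, prevalence_female: 0.085, prevalence_male: 0.063}
  - {id: insomnia, label: "Insomnia", icd10: [F51, G47], restriction: both, prevalence_female: 0.076, prevalence_male: 0.058}
  - {id: intestinal_diverticulosis, label: "Intestinal diverticulosis", icd10: [K57], restriction: both, prevalence_female: 0.064, prevalence_male: 0.062}
  - {id: hemorrhoids, label: "Hemorrhoids", icd10: [I84], restriction: both, prevalence_female: 0.052, prevalence_male: 0.068}
  - {id: somatoform_disorders, label: "Somatoform disorders", icd10: [F45], restriction: both, prevalence_female: 0.077, prevalence_male: 0.045}
  - {id: severe_hearing_loss, label: "Severe hearing loss", icd10: [H90, H91], restriction: both, prevalence_female: 0.038, prevalence_male: 0.052}
  - {id: dizziness, label: "Dizziness", icd10: [H81, R42], restriction: both, prevalence_female: 0.054, prevalence_male: 0.034}
  - {id: anxiety, label: "Anxiety", icd10: [F40, F41], restriction: both, prevalence_female: 0.037, prevalence_male: 0.016}
  - {id: sexual_dysfunction, label: "Sexual dysfunction", icd10: [F52, N48], restriction: male_only, prevalence_female: 0.0, prevalence_male: 0.045}
  - {id: hypertension, label: "Hypertension", icd10: [I10, I11, I12, I13, I15], restriction: both, prevalence_female: 0.693, prevalence_male: 0.694}
  - {id: lipid_metabolism_disorders, label: "Lipid metabolism disorders", icd10: [E78], restriction: both, prevalence_female: 0.467, prevalence_male: 0.480}
  - {id: diabetes_mellitus, label: "Diabetes mellitus", icd10: [E10, E11, E12, E13, E14], restriction: both, prevalence_female: 0.249, prevalence_male: 0.314}
  - {id: chronic_ischemic_heart_disease, label: "Chronic ischemic heart disease", icd10: [I20, I25], restriction: both, prevalence_female: 0.182, prevalence_male: 0.316}
  - {id: hyperuricemia_gout, label: "Hyperuricemia/Gout", icd10: [E79, M10], restriction: both, prevalence_female: 0.113, prevalence_male: 0.235}
  - {id: cardiac_arrhythmias, label: "Cardiac arrhythmias", icd10: [I47, I48, I49], restriction: both, prevalence_female: 0.155, prevalence_male: 0.200}
  - {id: atherosclerosis_paod, label: "Atherosclerosis/PAOD", icd10: [I70, I73], restriction: both, prevalence_female: 0.103, prevalence_male: 0.164}
  - {id: obesity, label: "Obesity", icd10: [E66], restriction: both, prevalence_female: 0.134, prevalence_male: 0.117}
  - {id: liver_diseases, label: "Liver diseases", icd10: [K70, K74, K76], restriction: both, prevalence_female: 0.099, prevalence_male: 0.137}
  - {id: cardiac_insufficiency, label: "Cardiac insufficiency", icd10: [I50], restriction: both, prevalence_female: 0.101, prevalence_male: 0.081}
  - {id: cerebral_ischemia_chronic_stroke, label: "Cerebral ischemia/Chronic stroke", icd10: [I63, I69, G45], restriction: both, prevalence_female: 0.073, prevalence_male: 0.103}
  - {id: neuropathies, label: "Neuropathies", icd10: [G50, G60, G62, G63], restriction: both, prevalence_female: 0.081, prevalence_male: 0.082}
  - {id: renal_insufficiency, label: "Renal insufficiency", icd10: [N18, N19], restriction: both, prevalence_female: 0.042, prevalence_male: 0.083}
  - {id: cardiac_valve_disorders, label: "Cardiac valve disorders", icd10: [I34, I35, I36, I37], restriction: both, prevalence_female: 0.052, prevalence_male: 0.060}
  - {id: severe_vision_reduction, label: "Severe vision reduction", icd10: [H25, H35, H40, H54], restriction: both, prevalence_female: 0.220, prevalence_male: 0.196}
  - {id: cancers, label: "Cancers", icd10: [C], restriction: both, prevalence_female: 0.148, prevalence_male: 0.212}
  - {id: urinary_incontinence, label: "Urinary incontinence", icd10: [N39, R32], restriction: both, prevalence_female: 0.071, prevalence_male: 0.035}
  - {id: thyroid_dysfunction, label: "Thyroid dysfunction", icd10: [E01, E03, E04, E05], restriction: both, prevalence_female: 0.18, prevalence_male: 0.08, synthetic_prevalence: true}
  - {id: dementia, label: "Dementia", icd10: [F00, F01, F03, G30], restriction: both, prevalence_female: 0.06, prevalence_male: 0.05, synthetic_prevalence: true}
  - {id: parkinsons_disease, label: "Parkinson's disease", icd10: [G20, G21], restriction: both, prevalence_female: 0.02, prevalence_male: 0.03, synthetic_prevalence: true}
  - {id: anemia, label: "Anemia", icd10: [D50, D51, D52, D53, D63, D64], restriction: both, prevalence_female: 0.08, prevalence_male: 0.05, synthetic_prevalence: true}
  - {id: hypotension_syncope, label: "Hypotension/Syncope", icd10: [I95, R55], restriction: both, prevalence_female: 0.04, prevalence_male: 0.03, synthetic_prevalence: true}
  - {id: migraine_chronic_headache, label: "Migraine/Chronic headache", icd10: [G43, G44], restriction: both, prevalence_female: 0.06, prevalence_male: 0.03, synthetic_prevalence: true}
  - {id: psoriasis, label: "Psoriasis", icd10: [L40], restriction: both, prevalence_female: 0.03, prevalence_male: 0.03, synthetic_prevalence: true}
  - {id: rheumatoid_arthritis, label: "Rheumatoid arthritis/Chronic polyarthritis", icd10: [M05, M06, M79], restriction: both, prevalence_female: 0.05, prevalence_male: 0.03, synthetic_prevalence: true}
  - {id: cholecystitis_gallstones, label: "Chronic cholecystitis/Gallstones", icd10: [K80, K81], restriction: both, prevalence_female: 0.08, prevalence_male: 0.04, synthetic_prevalence: true}
  - {id: chronic_bronchitis, label: "Chronic bronchitis/Bronchiectasis", icd10: [J41, J42, J47], restriction: both, prevalence_female: 0.04, prevalence_male: 0.06, synthetic_prevalence: true}
  - {id: tobacco_abuse, label: "Tobacco abuse", icd10: [F17], restriction: both, prevalence_female: 0.03, prevalence_male: 0.08, synthetic_prevalence: true}
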