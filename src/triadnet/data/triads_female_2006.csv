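section,group_a,group_b,group_c,oe_ratio,prevalence_pct
cardiometabolic,diabetes_mellitus,hyperuricemia_gout,liver_diseases,3.8,1.0
cardiometabolic,diabetes_mellitus,obesity,hyperuricemia_gout,3.7,1.4
cardiometabolic,hypertension,hyperuricemia_gout,renal_insufficiency,3.7,1.2
cardiometabolic,chronic_ischemic_heart_disease,cardiac_arrhythmias,cardiac_insufficiency,3.7,1.1
cardiometabolic,lipid_metabolism_disorders,hyperuricemia_gout,liver_diseases,3.1,1.6
cardiometabolic,diabetes_mellitus,chronic_ischemic_heart_disease,cardiac_insufficiency,3.0,1.4
cardiometabolic,diabetes_mellitus,chronic_ischemic_heart_disease,neuropathies,2.9,1.0
cardiometabolic,lipid_metabolism_disorders,cardiac_arrhythmias,cardiac_valve_disorders,2.8,1.0
cardiometabolic,hypertension,cardiac_arrhythmias,cardiac_valve_disorders,2.7,1.5
cardiometabolic,diabetes_mellitus,chronic_ischemic_heart_disease,hyperuricemia_gout,2.7,1.4
cardiometabolic,severe_vision_reduction,diabetes_mellitus,neuropathies,2.7,1.2
cardiometabolic,diabetes_mellitus,chronic_ischemic_heart_disease,atherosclerosis_paod,2.7,1.2
cardiometabolic,lipid_metabolism_disorders,obesity,hyperuricemia_gout,2.6,1.8
cardiometabolic,lipid_metabolism_disorders,diabetes_mellitus,hyperuricemia_gout,2.3,3.0
cardiometabolic,hypertension,obesity,hyperuricemia_gout,2.3,2.3
cardiometabolic,hypertension,hyperuricemia_gout,liver_diseases,2.3,1.8
cardiometabolic,lipid_metabolism_disorders,chronic_ischemic_heart_disease,cardiac_valve_disorders,2.3,1.0
cardiometabolic,hypertension,chronic_ischemic_heart_disease,renal_insufficiency,2.2,1.2
cardiometabolic,hypertension,atherosclerosis_paod,cerebral_ischemia_chronic_stroke,2.2,1.2
cardiometabolic,lipid_metabolism_disorders,hyperuricemia_gout,cardiac_insufficiency,2.2,1.2
cardiometabolic,hypertension,chronic_ischemic_heart_disease,cardiac_insufficiency,2.1,2.6
cardiometabolic,lipid_metabolism_disorders,chronic_ischemic_heart_disease,atherosclerosis_paod,2.1,1.8
cardiometabolic,diabetes_mellitus,chronic_ischemic_heart_disease,cardiac_arrhythmias,2.1,1.5
cardiometabolic,hypertension,diabetes_mellitus,renal_insufficiency,2.1,1.5
cardiometabolic,diabetes_mellitus,chronic_ischemic_heart_disease,obesity,2.1,1.3
cardiometabolic,lipid_metabolism_disorders,obesity,liver_diseases,2.1,1.3
cardiometabolic,lipid_metabolism_disorders,hyperuricemia_gout,atherosclerosis_paod,2.1,1.2
cardiometabolic,lipid_metabolism_disorders,liver_diseases,atherosclerosis_paod,2.1,1.0
cardiometabolic,hypertension,diabetes_mellitus,obesity,2.0,4.6
cardiometabolic,lipid_metabolism_disorders,chronic_ischemic_heart_disease,hyperuricemia_gout,2.0,1.9
cardiometabolic,hypertension,chronic_ischemic_heart_disease,cardiac_valve_disorders,2.0,1.3
cardiometabolic,severe_vision_reduction,diabetes_mellitus,atherosclerosis_paod,2.0,1.1
ads_pain,chronic_low_back_pain,depression,somatoform_disorders,2.6,1.7
ads_pain,chronic_low_back_pain,asthma_copd,allergies,2.4,1.4
ads_pain,chronic_low_back_pain,intestinal_diverticulosis,chronic_gastritis_gerd,2.4,1.1
ads_pain,chronic_low_back_pain,depression,insomnia,2.3,1.5
ads_pain,joint_arthrosis,depression,somatoform_disorders,2.3,1.1
ads_pain,chronic_low_back_pain,depression,dizziness,2.3,1.0
ads_pain,joint_arthrosis,depression,insomnia,2.3,1.0
ads_pain,chronic_low_back_pain,somatoform_disorders,chronic_gastritis_gerd,2.2,1.2
ads_pain,chronic_low_back_pain,lower_limb_varicosis,hemorrhoids,2.1,1.2
ads_pain,chronic_low_back_pain,gynaecological_problems,urinary_incontinence,2.1,1.2
ads_pain,chronic_low_back_pain,chronic_gastritis_gerd,insomnia,2.1,1.1
ads_pain,chronic_low_back_pain,gynaecological_problems,somatoform_disorders,2.0,1.2
ads_pain,depression,osteoporosis,chronic_gastritis_gerd,2.0,1.1
both,joint_arthrosis,obesity,hyperuricemia_gout,2.5,1.2
both,chronic_ischemic_heart_disease,lower_limb_varicosis,cardiac_insufficiency,2.5,1.0
both,joint_arthrosis,chronic_ischemic_heart_disease,cardiac_insufficiency,2.4,1.5
both,chronic_low_back_pain,hyperuricemia_gout,liver_diseases,2.3,1.2
both,hypertension,depression,anxiety,2.2,1.0
both,chronic_low_back_pain,obesity,hyperuricemia_gout,2.1,1.5
both,diabetes_mellitus,obesity,lower_limb_varicosis,2.1,1.5
both,joint_arthrosis,diabetes_mellitus,neuropathies,2.1,1.4
both,chronic_low_back_pain,depression,neuropathies,2.1,1.4
both,chronic_low_back_pain,neuropathies,chronic_gastritis_gerd,2.1,1.2
both,joint_arthrosis,obesity,lower_limb_varicosis,2.0,2.0
both,lipid_metabolism_disorders,asthma_copd,allergies,2.0,1.1
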