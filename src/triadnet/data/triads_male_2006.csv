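section,group_a,group_b,group_c,oe_ratio,prevalence_pct
cardiometabolic,obesity,hyperuricemia_gout,liver_diseases,3.5,1.3
cardiometabolic,chronic_ischemic_heart_disease,cardiac_arrhythmias,cardiac_insufficiency,3.3,1.7
cardiometabolic,diabetes_mellitus,atherosclerosis_paod,neuropathies,3.3,1.4
cardiometabolic,chronic_ischemic_heart_disease,cardiac_arrhythmias,cardiac_valve_disorders,3.2,1.2
cardiometabolic,diabetes_mellitus,obesity,liver_diseases,3.0,1.5
cardiometabolic,severe_vision_reduction,diabetes_mellitus,neuropathies,3.0,1.5
cardiometabolic,chronic_ischemic_heart_disease,atherosclerosis_paod,renal_insufficiency,2.9,1.2
cardiometabolic,chronic_ischemic_heart_disease,atherosclerosis_paod,cardiac_insufficiency,2.9,1.2
cardiometabolic,diabetes_mellitus,atherosclerosis_paod,renal_insufficiency,2.6,1.1
cardiometabolic,chronic_ischemic_heart_disease,hyperuricemia_gout,renal_insufficiency,2.5,1.5
cardiometabolic,chronic_ischemic_heart_disease,cardiac_arrhythmias,renal_insufficiency,2.4,1.3
cardiometabolic,chronic_ischemic_heart_disease,atherosclerosis_paod,cerebral_ischemia_chronic_stroke,2.4,1.3
cardiometabolic,diabetes_mellitus,atherosclerosis_paod,cerebral_ischemia_chronic_stroke,2.4,1.2
cardiometabolic,hypertension,renal_insufficiency,cardiac_insufficiency,2.4,1.1
cardiometabolic,lipid_metabolism_disorders,hyperuricemia_gout,liver_diseases,2.3,3.5
cardiometabolic,diabetes_mellitus,hyperuricemia_gout,liver_diseases,2.3,2.3
cardiometabolic,diabetes_mellitus,obesity,hyperuricemia_gout,2.3,1.9
cardiometabolic,lipid_metabolism_disorders,obesity,liver_diseases,2.3,1.7
cardiometabolic,diabetes_mellitus,hyperuricemia_gout,renal_insufficiency,2.3,1.4
cardiometabolic,diabetes_mellitus,cardiac_arrhythmias,cardiac_insufficiency,2.3,1.2
cardiometabolic,hypertension,urinary_incontinence,cancers,2.3,1.1
cardiometabolic,lipid_metabolism_disorders,hyperuricemia_gout,renal_insufficiency,2.2,2.1
cardiometabolic,diabetes_mellitus,chronic_ischemic_heart_disease,cardiac_insufficiency,2.2,1.8
cardiometabolic,hypertension,cardiac_arrhythmias,cardiac_valve_disorders,2.1,1.8
cardiometabolic,diabetes_mellitus,chronic_ischemic_heart_disease,renal_insufficiency,2.1,1.7
cardiometabolic,lipid_metabolism_disorders,cardiac_arrhythmias,cardiac_valve_disorders,2.1,1.2
cardiometabolic,chronic_ischemic_heart_disease,hyperuricemia_gout,cardiac_insufficiency,2.1,1.2
cardiometabolic,hyperuricemia_gout,liver_diseases,atherosclerosis_paod,2.1,1.1
cardiometabolic,hypertension,hyperuricemia_gout,renal_insufficiency,2.0,2.7
cardiometabolic,lipid_metabolism_disorders,obesity,hyperuricemia_gout,2.0,2.7
cardiometabolic,hypertension,obesity,liver_diseases,2.0,2.3
cardiometabolic,hypertension,cardiac_arrhythmias,cardiac_insufficiency,2.0,2.3
cardiometabolic,diabetes_mellitus,chronic_ischemic_heart_disease,neuropathies,2.0,1.7
cardiometabolic,lipid_metabolism_disorders,atherosclerosis_paod,cerebral_ischemia_chronic_stroke,2.0,1.6
ads_pain,chronic_low_back_pain,hemorrhoids,chronic_gastritis_gerd,2.5,1.0
ads_pain,chronic_low_back_pain,joint_arthrosis,hemorrhoids,2.3,1.6
ads_pain,chronic_low_back_pain,prostatic_hyperplasia,sexual_dysfunction,2.3,1.2
ads_pain,chronic_low_back_pain,joint_arthrosis,lower_limb_varicosis,2.2,2.5
ads_pain,chronic_low_back_pain,joint_arthrosis,intestinal_diverticulosis,2.2,1.4
ads_pain,chronic_low_back_pain,depression,chronic_gastritis_gerd,2.2,1.1
ads_pain,chronic_low_back_pain,prostatic_hyperplasia,hemorrhoids,2.1,1.6
ads_pain,chronic_low_back_pain,joint_arthrosis,insomnia,2.1,1.3
ads_pain,chronic_low_back_pain,joint_arthrosis,severe_hearing_loss,2.1,1.1
both,chronic_low_back_pain,cardiac_arrhythmias,cardiac_valve_disorders,2.0,1.0
both,chronic_ischemic_heart_disease,asthma_copd,cardiac_insufficiency,2.5,1.0
both,chronic_low_back_pain,joint_arthrosis,neuropathies,2.2,1.8
both,chronic_low_back_pain,obesity,liver_diseases,2.2,1.4
both,chronic_low_back_pain,atherosclerosis_paod,neuropathies,2.1,1.1
both,joint_arthrosis,obesity,hyperuricemia_gout,2.0,1.4
both,hyperuricemia_gout,liver_diseases,asthma_copd,2.0,1.1
both,hyperuricemia_gout,prostatic_hyperplasia,renal_insufficiency,2.0,1.1
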