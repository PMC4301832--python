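group_id,cluster,prev_total_pct,prev_female_pct,prev_male_pct,edges_female,degree_centrality_female_pct,edges_male,degree_centrality_male_pct,betweenness_female_pct,betweenness_male_pct
chronic_low_back_pain,ads_pain,43.7,47.1,41.0,16,8.0,16,9.2,28.4,32.2
joint_arthrosis,ads_pain,28.7,33.6,24.8,10,5.0,9,5.2,4.9,5.7
lower_limb_varicosis,ads_pain,16.4,22.7,11.5,7,3.5,2,1.1,3.1,0.0
prostatic_hyperplasia,ads_pain,,,28.1,,,5,2.9,,2.6
asthma_copd,ads_pain,15.3,14.1,16.3,3,1.5,4,2.3,0.4,0.1
depression,ads_pain,12.4,18.1,7.8,10,5.0,2,1.1,11.9,0.0
chronic_gastritis_gerd,ads_pain,10.8,10.8,10.8,7,3.5,3,1.7,2.7,0.1
osteoporosis,ads_pain,10.7,19.7,3.6,2,1.0,,,0.0,
gynaecological_problems,ads_pain,,16.6,,3,1.5,,,0.1,
allergies,ads_pain,7.3,8.5,6.3,3,1.5,,,0.4,
insomnia,ads_pain,6.6,7.6,5.8,4,2.0,2,1.1,0.2,0.0
intestinal_diverticulosis,ads_pain,6.3,6.4,6.2,2,1.0,2,1.1,0.0,0.0
hemorrhoids,ads_pain,6.1,5.2,6.8,2,1.0,4,2.3,0.0,0.4
somatoform_disorders,ads_pain,5.9,7.7,4.5,5,2.5,,,1.1,
severe_hearing_loss,ads_pain,4.6,3.8,5.2,,,2,1.1,,0.0
dizziness,ads_pain,4.2,5.4,3.4,2,1.0,,,0.0,
anxiety,ads_pain,2.5,3.7,1.6,2,1.0,,,0.0,
sexual_dysfunction,ads_pain,,,4.5,,,2,1.1,,0.0
hypertension,cardiometabolic,69.3,69.3,69.4,13,6.5,9,5.2,12.0,12.0
lipid_metabolism_disorders,cardiometabolic,47.4,46.7,48.0,11,5.5,8,4.6,5.8,1.4
diabetes_mellitus,cardiometabolic,28.5,24.9,31.4,14,7.0,11,6.3,5.8,5.0
chronic_ischemic_heart_disease,cardiometabolic,25.7,18.2,31.6,13,6.5,10,5.7,5.1,2.8
hyperuricemia_gout,cardiometabolic,18.1,11.3,23.5,11,5.5,12,6.9,5.2,7.8
cardiac_arrhythmias,cardiometabolic,18.0,15.5,20.0,6,3.0,8,4.6,0.2,4.3
atherosclerosis_paod,cardiometabolic,13.7,10.3,16.4,8,4.0,10,5.7,2.6,5.7
obesity,cardiometabolic,12.4,13.4,11.7,9,4.5,7,4.0,2.2,3.8
liver_diseases,cardiometabolic,12.0,9.9,13.7,7,3.5,8,4.6,2.0,4.5
cardiac_insufficiency,cardiometabolic,9.0,10.1,8.1,8,4.0,8,4.6,1.0,1.3
cerebral_ischemia_chronic_stroke,cardiometabolic,9.0,7.3,10.3,2,1.0,4,2.3,0.0,0.1
neuropathies,cardiometabolic,8.2,8.1,8.2,7,3.5,6,3.4,4.6,3.9
renal_insufficiency,cardiometabolic,6.5,4.2,8.3,4,2.0,9,5.2,0.0,2.6
cardiac_valve_disorders,cardiometabolic,5.7,5.2,6.0,4,2.0,5,2.9,0.1,2.2
severe_vision_reduction,none,20.6,22.0,19.6,3,1.5,2,1.1,0.1,0.0
cancers,none,18.4,14.8,21.2,,,2,1.1,,0.0
urinary_incontinence,none,5.1,7.1,3.5,2,1.0,2,1.1,0.0,0.0
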