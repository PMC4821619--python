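study_id,design,measure,outcome,exposure,estimate,ci_low,ci_high,ci_level,adjusted
bilik_2010,cohort,HR,myocardial_infarction,rosiglitazone_vs_pioglitazone,1.30,0.31,5.37,0.95,true
brownstein_2010,cohort,RR,myocardial_infarction,rosiglitazone_vs_pioglitazone,1.70,1.10,2.63,0.95,true
dormuth_2009,case_control,HR,myocardial_infarction,rosiglitazone_vs_pioglitazone,1.00,0.67,1.49,0.95,true
graham_2010,cohort,HR,myocardial_infarction,rosiglitazone_vs_pioglitazone,1.06,0.96,1.18,0.95,true
hsiao_2009,cohort,HR,myocardial_infarction,rosiglitazone_vs_pioglitazone,1.36,1.22,1.53,0.95,false
juurlink_2009,cohort,HR,myocardial_infarction,rosiglitazone_vs_pioglitazone,1.05,0.90,1.23,0.95,true
koro_2008,case_control,OR,myocardial_infarction,rosiglitazone_vs_pioglitazone,1.12,0.99,1.26,0.95,true
lipscombe_2007,case_control,OR,myocardial_infarction,rosiglitazone_vs_pioglitazone,1.27,1.02,1.58,0.95,false
margolis_2008,cohort,HR,myocardial_infarction,rosiglitazone_vs_pioglitazone,1.00,0.80,1.30,0.95,true
stockl_2009,case_control,OR,myocardial_infarction,rosiglitazone_vs_pioglitazone,1.26,0.79,2.00,0.95,true
tzoulaki_2009,cohort,HR,myocardial_infarction,rosiglitazone_vs_pioglitazone,1.34,0.86,2.09,0.95,true
walker_2008,cohort,HR,myocardial_infarction,rosiglitazone_vs_pioglitazone,1.21,0.95,1.54,0.95,true
wertz_2010,cohort,HR,myocardial_infarction,rosiglitazone_vs_pioglitazone,0.94,0.75,1.18,0.95,true
winkelmayer_2008,cohort,IRR,myocardial_infarction,rosiglitazone_vs_pioglitazone,1.08,0.93,1.25,0.95,true
ziyadeh_2009,cohort,HR,myocardial_infarction,rosiglitazone_vs_pioglitazone,1.41,1.13,1.75,0.95,true
bilik_2010,cohort,HR,heart_failure,rosiglitazone_vs_pioglitazone,0.69,0.28,1.69,0.95,true
graham_2010,cohort,HR,heart_failure,rosiglitazone_vs_pioglitazone,1.25,1.16,1.34,0.95,true
hsiao_2009,cohort,HR,heart_failure,rosiglitazone_vs_pioglitazone,1.40,1.15,1.71,0.95,false
juurlink_2009,cohort,HR,heart_failure,rosiglitazone_vs_pioglitazone,1.30,1.15,1.45,0.95,true
lipscombe_2007,case_control,OR,heart_failure,rosiglitazone_vs_pioglitazone,1.38,1.13,1.69,0.95,false
pantalone_2009,cohort,HR,heart_failure,rosiglitazone_vs_pioglitazone,0.84,0.52,1.35,0.95,true
tzoulaki_2009,cohort,HR,heart_failure,rosiglitazone_vs_pioglitazone,1.04,0.75,1.44,0.95,true
wertz_2010,cohort,HR,heart_failure,rosiglitazone_vs_pioglitazone,1.10,0.94,1.31,0.95,true
winkelmayer_2008,cohort,IRR,heart_failure,rosiglitazone_vs_pioglitazone,1.13,1.01,1.26,0.95,true
graham_2010,cohort,HR,mortality,rosiglitazone_vs_pioglitazone,1.14,1.05,1.24,0.95,true
juurlink_2009,cohort,HR,mortality,rosiglitazone_vs_pioglitazone,1.16,1.02,1.33,0.95,true
lipscombe_2007,case_control,OR,mortality,rosiglitazone_vs_pioglitazone,1.13,0.92,1.38,0.95,false
pantalone_2009,cohort,HR,mortality,rosiglitazone_vs_pioglitazone,1.23,0.79,1.92,0.95,true
tzoulaki_2009,cohort,HR,mortality,rosiglitazone_vs_pioglitazone,1.36,1.05,1.76,0.95,true
wertz_2010,cohort,HR,mortality,rosiglitazone_vs_pioglitazone,1.02,0.86,1.21,0.95,true
winkelmayer_2008,cohort,IRR,mortality,rosiglitazone_vs_pioglitazone,1.15,1.05,1.26,0.95,true
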