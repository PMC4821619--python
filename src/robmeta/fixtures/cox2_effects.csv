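study_id,design,measure,outcome,exposure,estimate,ci_low,ci_high,ci_level,adjusted
gislason_2006,cohort,OR,cv_event,celecoxib,2.06,1.73,2.45,0.95,true
graham_2005,case_control,OR,cv_event,celecoxib,0.84,0.67,1.04,0.95,true
hippisley_cox_2005,case_control,OR,cv_event,celecoxib,1.21,0.96,1.54,0.95,true
johnsen_2005,case_control,OR,cv_event,celecoxib,1.25,0.97,1.62,0.95,true
kimmel_2005,case_control,OR,cv_event,celecoxib,0.43,0.23,0.79,0.95,true
levesque_2005,case_control,RR,cv_event,celecoxib,0.99,0.85,1.16,0.95,true
mamdani_2003,case_control,RR,cv_event,celecoxib,0.90,0.70,1.16,0.95,true
mcgettigan_2006,case_control,OR,cv_event,celecoxib,1.11,0.59,2.11,0.95,true
ray_2002b,cohort,RR,cv_event,celecoxib,0.96,0.76,1.21,0.95,true
solomon_2004,case_control,OR,cv_event,celecoxib,0.93,0.84,1.02,0.95,true
gislason_2006,cohort,OR,cv_event,rofecoxib,2.29,1.99,2.65,0.95,true
graham_2005,case_control,OR,cv_event,rofecoxib,1.34,0.98,1.82,0.95,true
hippisley_cox_2005,case_control,OR,cv_event,rofecoxib,1.32,1.09,1.61,0.95,true
johnsen_2005,case_control,OR,cv_event,rofecoxib,1.80,1.47,2.21,0.95,true
kimmel_2005,case_control,OR,cv_event,rofecoxib,1.16,0.70,1.93,0.95,true
levesque_2005,case_control,RR,cv_event,rofecoxib,1.24,1.05,1.46,0.95,true
mamdani_2003,case_control,RR,cv_event,rofecoxib,1.00,0.80,1.25,0.95,true
mcgettigan_2006,case_control,OR,cv_event,rofecoxib,0.63,0.31,1.28,0.95,true
solomon_2004,case_control,OR,cv_event,rofecoxib,1.14,1.00,1.31,0.95,true
garcia_rodriguez_2004,case_control,OR,cv_event,meloxicam,0.97,0.60,1.56,0.95,true
levesque_2005,case_control,RR,cv_event,meloxicam,1.06,0.49,2.30,0.95,true
bak_2003,case_control,OR,cv_event,naproxen,0.70,0.40,1.22,0.95,true
fischer_2005,case_control,OR,cv_event,naproxen,0.96,0.66,1.38,0.95,true
garcia_rodriguez_2004,case_control,OR,cv_event,naproxen,0.89,0.64,1.24,0.95,true
graham_2005,case_control,OR,cv_event,naproxen,1.14,1.00,1.30,0.95,true
hippisley_cox_2005,case_control,OR,cv_event,naproxen,1.27,1.01,1.60,0.95,true
johnsen_2005,case_control,OR,cv_event,naproxen,1.50,0.99,2.29,0.95,true
kimmel_2004,case_control,OR,cv_event,naproxen,0.48,0.28,0.82,0.95,true
levesque_2005,case_control,RR,cv_event,naproxen,1.17,0.75,1.84,0.95,true
mamdani_2003,case_control,RR,cv_event,naproxen,1.00,0.60,1.67,0.95,true
ray_2002a,cohort,RR,cv_event,naproxen,0.95,0.82,1.09,0.95,true
ray_2002b,cohort,RR,cv_event,naproxen,0.93,0.82,1.06,0.95,true
schlienger_2002,case_control,OR,cv_event,naproxen,0.68,0.42,1.13,0.95,true
solomon_2002,case_control,ReR,cv_event,naproxen,0.84,0.72,0.98,0.95,true
watson_2002,case_control,OR,cv_event,naproxen,0.57,0.31,1.06,0.95,true
bak_2003,case_control,OR,cv_event,diclofenac,1.10,0.70,1.73,0.95,true
fischer_2005,case_control,OR,cv_event,diclofenac,1.23,1.00,1.51,0.95,true
garcia_rodriguez_2004,case_control,OR,cv_event,diclofenac,1.18,0.99,1.40,0.95,true
gislason_2006,cohort,OR,cv_event,diclofenac,2.19,1.93,2.49,0.95,true
hippisley_cox_2005,case_control,OR,cv_event,diclofenac,1.55,1.39,1.72,0.95,true
macdonald_2003,cohort,HR,cv_event,diclofenac,0.80,0.49,1.31,0.95,true
schlienger_2002,case_control,OR,cv_event,diclofenac,1.38,1.08,1.77,0.95,true
watson_2002,case_control,OR,cv_event,diclofenac,1.68,1.14,4.29,0.95,true
bak_2003,case_control,OR,cv_event,ibuprofen,1.30,1.00,1.69,0.95,true
curtis_2003,cohort,HR,cv_event,ibuprofen,0.84,0.70,1.01,0.95,true
fischer_2005,case_control,OR,cv_event,ibuprofen,1.16,0.92,1.46,0.95,true
garcia_rodriguez_2004,case_control,OR,cv_event,ibuprofen,1.06,0.87,1.29,0.95,true
gislason_2006,cohort,OR,cv_event,ibuprofen,1.39,1.27,1.53,0.95,true
graham_2005,case_control,OR,cv_event,ibuprofen,1.06,0.96,1.17,0.95,true
hippisley_cox_2005,case_control,OR,cv_event,ibuprofen,1.24,1.11,1.39,0.95,true
kimmel_2004,case_control,OR,cv_event,ibuprofen,0.52,0.39,0.69,0.95,true
macdonald_2003,cohort,HR,cv_event,ibuprofen,1.73,1.05,2.84,0.95,true
mcgettigan_2006,case_control,OR,cv_event,ibuprofen,0.98,0.53,1.81,0.95,true
ray_2002a,cohort,RR,cv_event,ibuprofen,1.15,1.02,1.28,0.95,true
ray_2002b,cohort,RR,cv_event,ibuprofen,0.91,0.78,1.06,0.95,true
schlienger_2002,case_control,OR,cv_event,ibuprofen,1.17,0.87,1.58,0.95,true
solomon_2002,case_control,ReR,cv_event,ibuprofen,1.02,0.88,1.18,0.95,true
watson_2002,case_control,OR,cv_event,ibuprofen,0.74,0.35,1.55,0.95,true
bak_2003,case_control,OR,cv_event,indomethacin,1.40,0.80,2.45,0.95,true
fischer_2005,case_control,OR,cv_event,indomethacin,1.36,0.82,2.25,0.95,true
garcia_rodriguez_2004,case_control,OR,cv_event,indomethacin,0.86,0.56,1.32,0.95,true
schlienger_2002,case_control,OR,cv_event,indomethacin,1.03,0.58,1.85,0.95,true
bak_2003,case_control,OR,cv_event,piroxicam,0.50,0.20,1.25,0.95,true
fischer_2005,case_control,OR,cv_event,piroxicam,0.95,0.53,1.69,0.95,true
garcia_rodriguez_2004,case_control,OR,cv_event,piroxicam,1.25,0.69,2.25,0.95,true
schlienger_2002,case_control,OR,cv_event,piroxicam,1.65,0.78,3.49,0.95,true
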