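study_id,confounding,selection,measurement_intervention,departures,missing_data,measurement_outcome,reported_result,overall
curtis_2003,moderate,moderate,low,moderate,moderate,low,low,serious
gislason_2006,low,low,low,low,low,low,low,low
macdonald_2003,moderate,low,low,low,low,low,low,moderate
mamdani_2003,moderate,low,low,low,low,low,low,moderate
ray_2002a,moderate,low,low,low,low,low,low,moderate
ray_2002b,moderate,low,low,low,low,low,low,moderate
bak_2003,serious,low,low,low,low,low,low,serious
fischer_2005,moderate,low,low,low,moderate,low,low,moderate
garcia_rodriguez_2000,moderate,low,low,low,moderate,low,low,moderate
garcia_rodriguez_2004,moderate,low,low,low,moderate,low,low,moderate
graham_2005,low,low,low,low,low,low,low,low
hippisley_cox_2005,moderate,low,low,low,moderate,low,low,moderate
johnsen_2005,moderate,low,low,low,low,low,low,moderate
kimmel_2004,moderate,moderate,moderate,low,moderate,low,low,serious
kimmel_2005,moderate,moderate,moderate,low,moderate,low,low,serious
levesque_2005,moderate,low,low,low,low,low,low,moderate
mcgettigan_2006,low,low,moderate,low,low,low,low,moderate
schlienger_2002,moderate,low,low,low,moderate,low,low,moderate
solomon_2002,moderate,moderate,low,moderate,low,low,moderate,serious
solomon_2004,low,moderate,low,low,low,low,low,moderate
watson_2002,low,low,low,low,moderate,low,low,moderate
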