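study_id,confounding,selection,measurement_intervention,departures,missing_data,measurement_outcome,reported_result,overall
bilik_2010,serious,low,low,low,low,low,low,serious
brownstein_2010,moderate,low,moderate,moderate,low,low,low,serious
graham_2010,low,low,low,low,low,low,low,low
hsiao_2009,critical,serious,low,moderate,low,low,low,critical
juurlink_2009,low,low,low,low,low,low,low,low
margolis_2008,moderate,serious,moderate,moderate,low,low,low,serious
pantalone_2009,serious,serious,low,moderate,serious,low,low,critical
tzoulaki_2009,low,low,low,low,moderate,low,low,moderate
walker_2008,low,low,low,low,low,low,low,low
wertz_2010,low,low,low,low,low,low,low,low
winkelmayer_2008,low,low,low,low,low,low,low,low
ziyadeh_2009,moderate,low,low,low,low,low,low,moderate
dormuth_2009,low,low,low,low,low,low,low,low
koro_2008,moderate,moderate,low,low,low,low,serious,serious
lipscombe_2007,moderate,low,low,low,low,low,low,moderate
stockl_2009,moderate,low,low,low,low,low,low,moderate
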