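key,mode,value
rr_lit,walking,0.9
rr_lit,cycling,0.9
at_lit,walking,168.0
at_lit,cycling,100.0
cap,walking,0.3
cap,cycling,0.45
ventilation_active,walking,1.37
ventilation_active,cycling,2.55
traffic_factor,walking,1.6
traffic_factor,cycling,2.0
ventilation_rest,,0.61
daily_ventilation,,16.0
counterfactual_traffic_factor,,2.5
rr_ap_per_10,,1.07
pa_rr_ap_adjustment,,1.0
p_exposed_default,,0.001
buildup_years_default,,5.0
uptake_years_default,,1.0
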