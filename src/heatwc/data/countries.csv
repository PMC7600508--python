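country_id,currency,mortality_rate_20_44,mortality_rate_45_64,mortality_rate_45_74,mortality_rate_20_64,mortality_rate_20_74,pm25_background,cycling_fatality_rate_per_100Mkm,gdp_pc_2005_ppp,ppp_2005,inflation_2005_2015,income_growth_2005_2015,car_ef_operational,car_ef_fuel_supply,car_ef_lifecycle,car_occupancy,bus_ef_operational,bus_ef_fuel_supply,bus_ef_lifecycle,bus_occupancy,motorcycle_ef_operational,motorcycle_ef_fuel_supply,motorcycle_ef_lifecycle,motorcycle_occupancy,scc_override
ZZA,ZZAD,0.001023,0.008159,0.012085,0.003737,0.005454,19.314,1.0456,43806.4,0.8179,0.1256,0.0734,189.41,25.4,38.92,1.637,786.33,154.6,82.64,18.871,98.3,24.4,29.06,1.053,
ZZB,ZZBD,0.001291,0.007677,0.01247,0.002126,0.003381,20.746,1.6016,41503.1,1.3084,0.1844,0.2383,196.4,27.78,31.39,1.603,940.35,127.55,90.62,12.557,123.9,22.04,28.45,1.069,
ZZC,ZZCD,0.000863,0.008172,0.012936,0.003935,0.006243,18.083,,37858.3,1.2825,0.2825,0.1392,209.15,37.19,38.58,1.67,1073.76,156.44,118.49,14.039,97.54,27.3,21.04,1.069,
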