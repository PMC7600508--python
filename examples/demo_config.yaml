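# Two-case demo: a city cycling intervention in synthetic country ZZA.
# Daily cycling rises from 10 to 20 minutes per person over a 5-year uptake,
# assessed over 20 years across all four pathways.
country: ZZA
scale: city
city: Demoville
comparison: two_case
modes: [cycling, walking]
pathways: [physical_activity, air_pollution, crash, carbon]
timeframe:
  reference_year: 2020
  assessment_years: 20
  uptake_years: 5
  buildup_years: 5
  discount_rate: 0.05
  discount_year: 2020
population:
  size: 200000
  type: general_population
  age_range: average
travel:
  cycling:
    reference: {mode: cycling, unit: minutes, value: 10}
    comparison: {mode: cycling, unit: minutes, value: 20}
  walking:
    reference: {mode: walking, unit: minutes, value: 15}
    comparison: {mode: walking, unit: minutes, value: 18}
adjustments:
  prop_in_traffic: 0.6
  prop_transport_purpose: 0.7
  mode_shift:
    new_trips: 0.1
    reassigned_trips: 0.1
    from_walking: 0.1
    from_car: 0.4
    from_bus: 0.3
crash:
  risk_change: -0.2
monetization:
  investment_cost: 50000000
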