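# Methods

`heatwc` estimates the mortality and carbon consequences of specified
amounts of walking and cycling in a population, using a comparative risk
assessment on aggregated (population-mean) data. Two scenarios are
contrasted — a *reference case* and a *comparison case* — and the impact is
the difference in outcomes attributable to active travel between them. A
*single-case* assessment treats the observed travel as a steady state and
contrasts it against zero active travel; a *two-case* assessment contrasts
two specified travel levels. Baseline mortality rates are held constant
over the assessment period; only mortality (not morbidity) is assessed, and
only for adults (20–64 for cycling, 20–74 for walking, with three coarse
age-range options), because mortality below 20 is negligible and risks
above the upper bounds rise steeply enough to dominate results.

## Standard units and inputs

Every travel input is converted to **minutes per person per day** and
**kilometres per person per day** before any impact calculation. Nine
input units are accepted (minutes, hours, km, miles, trips, short-term
counts, steps [walking only], frequency categories, mode share). The
conversions use overridable defaults: speeds 5.3 km/h walking and
14.0 km/h cycling, trip distances 1.0 km walking and 3.0 km cycling, step
length 0.7 m. These are operational defaults taken from the tool's
methodological guidance rather than primary literature values, and every
one of them is a plain registry/config entry.

Count data are accepted only for sub-city assessments, and the user must
state what each counted pass represents (locations × minutes per count,
spread over the assessed population): area-wide extrapolation from counts
is not attempted. Frequency categories are resolved as a
population-weighted mean of days/7 × minutes per active day, with shares
required to sum to 100% ± 0.1.

## Adjustments

All adjustments default to neutral values:

* **Trend exclusion** removes a stated fraction of the
  reference→comparison *increment* (not of absolute levels), reflecting
  growth that would have happened without the assessed intervention.
* **Count correction** rescales count-derived volumes for seasonal or
  geographic distortion; it is applied after unit standardization.
* **Physical-activity substitution** scales the PA pathway's effective
  volumes by (1 − substitution fraction) only. Pollution intake, crash
  exposure and replaced vehicle-km accrue to the travel itself regardless
  of whether it displaces other exercise, so those pathways use
  unsubstituted volumes.
* **Traffic/purpose splits** (proportion in traffic, proportion for
  transport purposes; both default 1.0, the conservative case) feed the
  air-pollution exposure model.
* **Mode shift** attributes kilometre contrasts to the trips they replace.
  Defaults: 40% from car, 30% from bus, 10% from walking, 10% new
  (induced) trips, 10% reassigned trips. New and reassigned trips avoid no
  motorized travel. The defaults are round, urban-plausible placeholders
  intended to be replaced by local data.

## Pathways

**Physical activity.** The literature all-cause-mortality relative risk
(default 0.90 at 168 min/week walking, 0.90 at 100 min/week cycling;
user-guide-derived, configurable) is rescaled linearly in the risk
*reduction*: RR = 1 − min((1 − RR_lit) × AT/AT_lit, cap), with caps 0.30
(walking) and 0.45 (cycling). The literal proportional form
RR_lit × AT/AT_lit would send RR to zero at zero volume; scaling the
reduction is the form consistent with a capped linear dose–response and
with the attributable-risk algebra. Attributable deaths use the
population attributable risk formula with exposed fraction P_e (default
0.001 for general populations, 1.0 when volumes describe active
travellers only): MR_u = MR_pop/[1 − P_e(1 − RR)], MR_e = RR·MR_u,
D_attr = (MR_e − MR_u)·POP. At P_e = 0.001 this is within 0.1% of the
MR_pop approximation. When the air-pollution pathway is co-assessed, RR_lit
is multiplied by a configurable adjustment (default 1.0; the difference is
negligible) because the underlying cohort estimates did not exclude
concurrent pollution exposure.

**Air pollution.** Walking and cycling raise PM2.5 intake mainly through
ventilation: 1.37 m³/h walking and 2.55 m³/h cycling versus 0.61 m³/h at
rest, within a 16 m³ total daily volume (the last two user-guide-derived).
Travel in traffic sees background × 1.6 (walking) or × 2.0 (cycling);
travel away from traffic sees background. The counterfactual applies rest
ventilation to the exposure the travel replaces — transport-purpose
minutes counterfactually sit in traffic (in-vehicle factor 2.5 on
background, user-guide-derived), leisure minutes at background — because
the excess intake is driven by the ventilation contrast. The excess
intake is expressed as an equivalent long-term concentration
ΔC_eq = (min/60)·[V_act·C_act − V_rest·C_cf]/V_day, which can be negative
(active travel away from traffic replacing in-car time yields a benefit;
it is reported, not clamped). ΔC_eq scales a per-10-µg/m³ relative risk
(default 1.07, user-guide-derived) linearly, and the same attributable-risk
machinery yields deaths caused. Only PM2.5 is modelled; mode-shift effects
on ambient concentrations and general-population health are out of scope.

**Crash.** Cyclist fatality rates per 100 million person-km (available
for selected countries only) are multiplied by the assessed person-km.
Where a country has no rate the pathway refuses explicitly — it never
contributes a silent zero. Pedestrian rates are not provided, and
sub-city crash assessment is refused because exposure-adjusted rates
cannot be estimated reliably at that scale. A user-specified relative
risk change (e.g. −0.3) interpolates linearly from the base rate in year 1
to the changed rate in the final year, over the full assessment period.
Fault attribution and non-fatal injuries are out of scope.

**Carbon.** Mode-shifted motorized person-km are valued with static
per-country emission factors split into operational, fuel-supply and
vehicle-lifecycle components (g CO2e per vehicle-km, divided by
occupancy). The registry carries factors for car, bus and motorcycle; the
residual "other motorized" category is valued like a car. A traffic
condition multiplier (free-flow 0.9, urban 1.0, congested 1.15) scales the
operational component, and a detour factor (default 1.0) accounts for
motorized routes being longer than the active route. The active mode's
own lifecycle emissions (default 0 g/km) are netted out; a negative
balance is flagged by sign, not clamped. Static factor tables are a
deliberate simplification of fleet-projection and speed–emission-curve
databases; optional per-year factors can be added as extra registry
columns without changing the engine.

## Temporality

Assessment years k = 1..N map to calendar years reference_year + k, with
impacts attributed at year-end (this fixes the discount exponents).

* **Uptake** (default 1 year): travel levels interpolate linearly,
  value(k) = ref + (comp − ref)·min(k/u, 1), reaching the comparison level
  in year u.
* **Build-up** (default 5 years, expert-consensus lag): achieved travel
  volumes need time to develop their full mortality effect. The realized
  annual PA/AP impact ramps linearly from zero to the full steady-state
  impact over u + b years: impact(k) = steady × min(k/(u+b), 1). With a
  5-year uptake and 5-year build-up the full annual impact first occurs in
  year 10; after a step change it first occurs in year b. A per-year
  moving-average formulation was considered and rejected because it
  reaches the full effect one year before the uptake + build-up endpoint
  that the combined schedule is defined to honour; the single linear ramp
  reproduces that endpoint exactly and keeps the discounted totals within
  a few percent of the moving-average variant.
* Build-up applies to the physical-activity and air-pollution pathways
  only. Crash fatalities follow the uptake-scheduled volumes and the
  linearly interpolated rate; carbon follows uptake alone (emissions
  respond immediately to travel).
* Single-case assessments are steady states: uptake and build-up are
  forced to zero.
* **Discounting** divides year-k money by (1 + r)^(year − discount_year)
  (default rate 5%/year, default discount year = the reference year);
  values before the discount year are inflated.

## Monetization

Country VSLs are derived from an OECD-average 2005 base value of USD
3.013 million via an income-elasticity benefit transfer (elasticity 0.8,
OECD-average 2005 GDP/capita at PPP of USD 30,801), converted with the
2005 PPP rate and brought to 2015 price/income levels with country
inflation and real-income growth. The result is in local currency at
2015 prices; no further FX conversion is applied, and any projection
beyond 2015 is left to an explicit user override of the VSL. Deaths
prevented enter positively, deaths caused (pollution, crashes) negatively.

Avoided CO2e is valued at the social cost of carbon of its emission year:
default schedule 44 USD_2015/t in 2015 rising linearly to 66 USD_2015/t in
2030, held constant outside the anchors (constant extrapolation is the
conservative choice in the absence of guidance). Because the SCC is a
global damage value in USD_2015 while the VSL is national and in local
currency, health and carbon subtotals are kept separate before the
combined total. The benefit–cost ratio divides the combined *net*
discounted value (harms subtracted) by the investment cost, and is
reported only when a cost is supplied.

## Synthetic background registry

The bundled registry (3 countries, fixed seed) emulates the role of the
WHO/World Bank background databases with synthetic but range-plausible
values: per-age-band mortality rates, ambient PM2.5 (6–25 µg/m³), cyclist
fatality rates (0.5–2.5 per 100 Mkm; one country deliberately lacks a
rate so the crash refusal path is exercised), VSL inputs
(GDP 15–45k USD PPP, inflation 10–30%, growth 5–25%), and car/bus/
motorcycle emission factors in typical European ranges. The generator is
deterministic given a seed and its files round-trip exactly through the
loader. What it does *not* emulate: correlations between country
indicators, city-level pollution heterogeneity, year trends in mortality
or fleets, and real country identities — so passing tests demonstrate the
calculation chain, not the realism of any particular country's inputs.

## Numerical choices and degenerate inputs

* Frequency-category shares must sum to 100% ± 0.1; mode-shift shares to
  1 ± 1e-9.
* The PAF denominator 1 − P_e(1 − RR) must be positive; violations raise.
* A one-year assessment uses the comparison crash rate directly (the
  interpolation endpoint).
* All schedules are closed-form and vectorized; a brute-force year-loop
  oracle in the test suite agrees with them to 1e-9 over 1,000 random
  configurations.
* Reports are deterministic: identical config + registry give
  byte-identical JSON, checked against a committed golden file.

## Problem sizes

The shipped demo and test scenarios use populations of 10⁵–2×10⁵ people,
20-year horizons and 3-country registries — the scale at which the tool's
users run city/country appraisals; all computations are closed-form per
year, so runtime is negligible at any realistic size.

## Known limitations

Mortality only; adults only; linear dose–response with hard caps; no
safety-in-numbers effects; no ambient-concentration feedback from mode
shift; static emission factors; crash pathway limited to cycling in
countries with rates; the age structure of the assessed population enters
only through the three coarse age-range options.
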