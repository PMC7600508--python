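# heatwc

Health economic assessment of walking and cycling: a scriptable engine
that estimates premature deaths prevented (or caused) by active travel in
a population — via physical-activity benefits, excess air-pollution intake
and cycling crash risk — plus the CO2e avoided by shifting trips away from
motorized modes, and monetizes all of it with country-specific values of
statistical life and a social cost of carbon schedule.

It is written for transport and public-health planners, researchers and
advocates who need defensible ballpark appraisals of walking/cycling
scenarios (status quo, before/after, or hypothetical) from minimal inputs:
travel volumes in whatever unit they were collected, a population size,
and a country's background data.

## The model in brief

Impacts are comparative risk assessments between a *reference* and a
*comparison* case. For the physical-activity pathway, the relative risk
for all-cause mortality is scaled linearly in the risk reduction and
capped,

    RR = 1 − min((1 − RR_lit) · AT/AT_lit, cap),      cap = 0.30 walk / 0.45 cycle

and attributable deaths follow the population attributable risk formula

    MR_u = MR_pop / [1 − P_e (1 − RR)],   MR_e = RR · MR_u,
    D_attr = (MR_e − MR_u) · POP.

Air-pollution harm converts excess PM2.5 intake while travelling
(elevated ventilation, in-traffic concentrations) into an equivalent
long-term concentration that scales a per-10-µg/m³ relative risk; crash
harm multiplies per-100-million-km cyclist fatality rates by assessed
person-km; carbon benefit values mode-shifted vehicle-km with
operational + fuel-supply + lifecycle emission factors. Impacts unroll
over an assessment period with linear uptake of travel, a linear build-up
of health effects (full impact after uptake + build-up years), and
discounting of monetized values; VSL transfers use
`VSL = 3.013M USD × (Y_c/Y_OECD)^0.8 × PPP × (1+ΔP) × (1+ΔY)^0.8`.
See `docs/methods.md` for the full account.

## Worked example

The repository ships a synthetic three-country background registry (the
package works entirely offline) and a demo scenario,
`examples/demo_config.yaml`: a city of 200,000 people where daily cycling
rises from 10 to 20 minutes per person and walking from 15 to 18, over a
5-year uptake, assessed 2021–2040 across all four pathways, with a
50M investment cost.

```bash
heat validate examples/demo_config.yaml
heat run examples/demo_config.yaml --out report/ --format csv
```

Key numbers from the resulting `report.json` (synthetic country `ZZA`,
local currency `ZZAD`):

| quantity | value | meaning |
|---|---|---|
| cycling, physical activity | 811.1 deaths prevented | 20-year total across the build-up ramp |
| cycling, air pollution | 46.2 deaths caused | extra PM2.5 intake while cycling |
| cycling, crash | 25.0 deaths caused | fatality rate × person-km, 20% risk improvement |
| cycling, carbon | 239,979 t CO2e avoided | 70% of shifted km replace car/bus travel |
| VSL | 3,891,087 ZZAD | income-elasticity benefit transfer, 2015 prices |
| combined net value | 2.068 × 10⁹ ZZAD | discounted to 2020 at 5%/yr |
| benefit–cost ratio | 41.4 | net discounted value / 50M investment |

The physical-activity benefit dwarfs the pollution and crash harms — the
typical finding for realistic urban scenarios — and the report's `audit`
section exposes every intermediate (standardized volumes, relative risks,
per-year series) for inspection.

Library use mirrors the CLI:

```python
import yaml
from heatwc import AssessmentConfig, load_default_registry, run_assessment

config = AssessmentConfig.from_dict(yaml.safe_load(open("examples/demo_config.yaml")))
result = run_assessment(config, load_default_registry())
print(result.monetized.combined_total, result.monetized.benefit_cost_ratio)
```

`heat fixtures --seed 7 --out myregistry/` writes a fresh synthetic
registry; point `heat run --registry myregistry/` at it, or at your own
`constants.csv`/`countries.csv` (optionally layered with
`overrides.yaml`).

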