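"""Air-pollution pathway: deaths caused by excess PM2.5 intake while
walking or cycling.

Active travellers breathe more (mode-specific ventilation rates of
1.37 m³/h walking, 2.55 m³/h cycling vs 0.61 m³/h at rest) and part of
their travel happens in traffic, where concentrations are elevated above
the urban background by a factor of 1.6 (walking) or 2.0 (cycling).  The
excess daily intake relative to the counterfactual activity it replaces is
expressed as an equivalent long-term concentration increment

    ΔC_eq = (minutes/60) × [V_active × C_active − V_rest × C_counterfactual]
            / daily_ventilation,

which scales a per-10-µg/m³ relative risk linearly.  Transport-purpose
travel is assumed to replace time spent in traffic (in-vehicle factor on
background), leisure travel to replace background exposure.  ΔC_eq may be
negative — e.g. cycling away from traffic replacing in-car time — in which
case the pathway yields a benefit; it is reported as such, not clamped.
The attributable-deaths machinery is shared with the physical-activity
pathway, with relative risks above one.
"""

from __future__ import annotations

from pydantic import BaseModel, Field

from .physical_activity import attributable_deaths


class APConstants(BaseModel):
    """Exposure constants for one active mode."""

    ventilation_active: float = Field(gt=0, description="m³/hour while travelling")
    ventilation_rest: float = Field(default=0.61, gt=0, description="m³/hour at rest")
    daily_ventilation: float = Field(default=16.0, gt=0, description="m³/day")
    traffic_factor: float = Field(ge=1, description="in-traffic multiplier on background")
    counterfactual_traffic_factor: float = Field(default=2.5, ge=1)
    rr_ap_per_10: float = Field(default=1.07, ge=1, description="RR per 10 µg/m³ PM2.5")


class APExposureInput(BaseModel):
    """Exposure description for one case of an air-pollution assessment."""

    mode: str
    minutes_per_day: float = Field(ge=0)
    pm25_background: float = Field(ge=0, description="µg/m³")
    prop_in_traffic: float = Field(default=1.0, ge=0, le=1)
    prop_transport_purpose: float = Field(default=1.0, ge=0, le=1)
    constants: APConstants


def active_concentration(inp: APExposureInput) -> float:
    """PM2.5 concentration experienced while travelling actively (µg/m³).

    The in-traffic share sees background × traffic factor, the remainder
    sees plain background.
    """
    c = inp.constants
    return inp.pm25_background * (
        inp.prop_in_traffic * c.traffic_factor + (1.0 - inp.prop_in_traffic)
    )


def counterfactual_concentration(inp: APExposureInput) -> float:
    """Concentration in the activity the travel replaces (µg/m³).

    Transport-purpose minutes counterfactually sit in traffic (in-vehicle
    factor on background); leisure minutes sit at background.
    """
    c = inp.constants
    return inp.pm25_background * (
        inp.prop_transport_purpose * c.counterfactual_traffic_factor
        + (1.0 - inp.prop_transport_purpose)
    )


def equivalent_excess_concentration(inp: APExposureInput) -> float:
    """Long-term-equivalent excess PM2.5 concentration, µg/m³.

    Excess daily intake (active minus counterfactual) divided by the total
    daily ventilation volume.  Negative when the replaced activity was more
    exposed than the active travel.
    """
    c = inp.constants
    hours = inp.minutes_per_day / 60.0
    intake_active = c.ventilation_active * active_concentration(inp)
    intake_counterfactual = c.ventilation_rest * counterfactual_concentration(inp)
    return hours * (intake_active - intake_counterfactual) / c.daily_ventilation


def ap_rr(delta_c_eq: float, rr_ap_per_10: float) -> float:
    """Relative risk for a concentration increment, linear in ΔC_eq."""
    if rr_ap_per_10 < 1:
        raise ValueError("rr_ap_per_10 must be >= 1")
    return 1.0 + (rr_ap_per_10 - 1.0) * delta_c_eq / 10.0


def case_rr(inp: APExposureInput) -> float:
    """Relative risk of one exposure case."""
    return ap_rr(equivalent_excess_concentration(inp), inp.constants.rr_ap_per_10)


def ap_impact(
    ref: APExposureInput,
    comp: APExposureInput,
    mr_pop: float,
    p_e: float,
    pop: float,
) -> float:
    """Steady-state annual deaths caused by the exposure contrast.

    D_attributed(comparison) − D_attributed(reference); positive = harm
    (more pollution intake in the comparison case).
    """
    d_ref = attributable_deaths(case_rr(ref), mr_pop, p_e, pop).d_attributed
    d_comp = attributable_deaths(case_rr(comp), mr_pop, p_e, pop).d_attributed
    return d_comp - d_ref
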