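"""Carbon pathway: CO2e avoided by shifting motorized travel to active modes.

Kilometre contrasts attributed to motorized source modes (via the
mode-shift shares) are converted to avoided emissions using static
per-country emission factors split into operational (in-use), fuel-supply
and vehicle-lifecycle components, expressed per vehicle-km and divided by
occupancy.  A traffic-condition multiplier scales the operational
component, and a detour factor accounts for motorized routes being longer
than the active route they replace.  Induced (new) and reassigned trips
avoid nothing.  The active mode's own lifecycle emissions (default zero)
are netted out; a negative balance is reported as such, never clamped.
"""

from __future__ import annotations

from typing import Literal, Mapping

from pydantic import BaseModel, Field

from .registry import ModeEmissionFactors
from .temporal import TimeFrame, YearSeries, uptake_series

TrafficCondition = Literal["free_flow", "urban", "congested"]

#: Multipliers on the operational emission factor by traffic condition.
TRAFFIC_CONDITION_FACTOR: dict[str, float] = {
    "free_flow": 0.9,
    "urban": 1.0,
    "congested": 1.15,
}

GRAMS_PER_TONNE = 1e6


class CarbonParams(BaseModel):
    """Emission-factor context for one assessment."""

    factors: dict[str, ModeEmissionFactors]
    #: Lifecycle emissions of the active mode itself, g CO2e per person-km.
    active_mode_ef: float = Field(default=0.0, ge=0)
    #: Motorized route length relative to the active route length.
    detour_factor: float = Field(default=1.0, gt=0)
    traffic_condition: TrafficCondition = "urban"

    def factor_for(self, mode: str) -> ModeEmissionFactors:
        # the residual "other_motorized" category is valued like a car
        key = "car" if mode == "other_motorized" else mode
        if key not in self.factors:
            raise KeyError(f"no emission factors for motorized mode {mode!r}")
        return self.factors[key]


def carbon_avoided(shifted_km_per_day: Mapping[str, float], params: CarbonParams) -> float:
    """Tonnes CO2e avoided per year by the given motorized person-km/day.

    Per source mode m:
    km_m × detour × (ef_op × traffic + ef_fuel + ef_lifecycle)_m / occupancy_m
    minus the active mode's own per-km emissions, × 365 / 1e6.
    """
    tc = TRAFFIC_CONDITION_FACTOR[params.traffic_condition]
    grams_per_day = 0.0
    for mode, km in shifted_km_per_day.items():
        if km == 0:
            continue
        ef = params.factor_for(mode)
        per_vkm = ef.ef_operational * tc + ef.ef_fuel_supply + ef.ef_lifecycle
        grams_per_day += km * params.detour_factor * per_vkm / ef.occupancy
        grams_per_day -= km * params.active_mode_ef
    return grams_per_day * 365.0 / GRAMS_PER_TONNE


def carbon_impact(
    ref_tonnes_per_year: float, comp_tonnes_per_year: float, tf: TimeFrame
) -> YearSeries:
    """Per-year avoided tonnes on the uptake schedule (no build-up lag).

    Emissions respond immediately to travel, so only uptake applies; the
    impact is the comparison-minus-reference avoided emissions each year.
    """
    sched = uptake_series(ref_tonnes_per_year, comp_tonnes_per_year, tf)
    return YearSeries(sched.start_year, sched.values - ref_tonnes_per_year)
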