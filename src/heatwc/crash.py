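"""Crash pathway: cycling fatalities from per-distance fatality rates.

Fatality rates (fatalities per 100 million person-km cycled) are available
only for selected countries; where the registry has none the pathway
refuses explicitly rather than silently contributing zero.  The pathway is
offered for cycling only — pedestrian rates are not provided — and not at
the sub-city scale, where exposure-adjusted rates cannot be estimated
reliably.  A user-specified relative change in crash risk between the
cases is interpolated linearly over the assessment period.
"""

from __future__ import annotations

from pydantic import BaseModel, Field

from .registry import CYCLING
from .temporal import TimeFrame, YearSeries, crash_risk_series, uptake_series

#: Person-km per rate unit (rates are fatalities per 100 million km).
RATE_DENOMINATOR = 1e8


class CrashPathwayUnavailable(ValueError):
    """No fatality rate for this country/mode — pathway refused, not zeroed."""


class CrashInput(BaseModel):
    """One case of a crash-risk assessment."""

    mode: str = CYCLING
    km_per_person_day: float = Field(ge=0)
    pop: float = Field(gt=0)
    fatality_rate: float | None = Field(
        default=None, ge=0, description="fatalities per 100 million person-km"
    )
    #: Fractional rate change reference→comparison (e.g. −0.3 = 30% safer).
    risk_change: float = Field(default=0.0, ge=-1)

    def require_rate(self) -> float:
        if self.mode != CYCLING:
            raise CrashPathwayUnavailable(
                f"crash pathway is available for cycling only, not {self.mode!r}"
            )
        if self.fatality_rate is None:
            raise CrashPathwayUnavailable(
                "no cycling fatality rate available for this country; "
                "supply one to assess the crash pathway"
            )
        return self.fatality_rate


def crash_fatalities(inp: CrashInput, year_rate: float | None = None) -> float:
    """Annual fatalities attributable to the assessed cycling volume.

    km/person/day × 365 × persons × rate / 1e8.
    """
    rate = inp.require_rate() if year_rate is None else year_rate
    return inp.km_per_person_day * 365.0 * inp.pop * rate / RATE_DENOMINATOR


def crash_impact(ref: CrashInput, comp: CrashInput, tf: TimeFrame) -> YearSeries:
    """Per-year deaths caused by the travel contrast (positive = harm).

    The comparison volume follows the uptake schedule and its fatality rate
    interpolates linearly to ``rate × (1 + risk_change)`` by the final
    year; the reference case keeps the base rate throughout.
    """
    if ref.pop != comp.pop:
        raise ValueError("reference and comparison cases must share the population")
    base_rate = ref.require_rate()
    comp_base = comp.require_rate()
    km = uptake_series(ref.km_per_person_day, comp.km_per_person_day, tf)
    rates = crash_risk_series(comp_base, comp_base * (1.0 + comp.risk_change), tf)
    comp_fatalities = km.values * 365.0 * comp.pop * rates.values / RATE_DENOMINATOR
    ref_fatalities = (
        ref.km_per_person_day * 365.0 * ref.pop * base_rate / RATE_DENOMINATOR
    )
    return YearSeries(tf.reference_year + 1, comp_fatalities - ref_fatalities)
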