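"""Physical-activity pathway: deaths prevented by walking/cycling.

The all-cause-mortality relative risk from the literature (RR_lit at a
reference weekly volume AT_lit) is rescaled to the assessed volume with a
linear dose–response on the risk *reduction*,

    RR = 1 − min((1 − RR_lit) × AT/AT_lit, cap),

capped at a maximum reduction (0.30 walking, 0.45 cycling).  Note the naive
reading "RR = RR_lit × AT/AT_lit" would drive RR to zero at zero volume;
scaling the reduction is the form consistent with a capped linear
dose–response and with the population-attributable-fraction algebra below.

Attributable deaths follow the population attributable risk formula: with
exposed fraction P_e and population mortality rate MR_pop,

    MR_u = MR_pop / [1 − P_e (1 − RR)]        (unexposed rate)
    MR_e = RR × MR_u                          (exposed rate)
    D_attributed = (MR_e − MR_u) × POP

D_attributed is negative when travel is beneficial (deaths prevented).
With the default P_e = 0.001 the denominator is ≈ 1 and
D_attributed ≈ MR_pop × POP × (RR − 1).
"""

from __future__ import annotations

from dataclasses import dataclass

from pydantic import BaseModel, Field, model_validator


class PAError(ValueError):
    pass


def scale_rr(rr_lit: float, at_lit: float, at_heat: float, cap: float) -> float:
    """Relative risk at the assessed weekly volume ``at_heat`` (min/week)."""
    if at_lit <= 0:
        raise PAError("at_lit must be > 0")
    if at_heat < 0:
        raise PAError("at_heat must be >= 0")
    reduction = (1.0 - rr_lit) * at_heat / at_lit
    return 1.0 - min(reduction, cap)


@dataclass(frozen=True)
class AttributableDeaths:
    """Intermediate quantities of the attributable-risk calculation."""

    rr_heat: float
    mr_u: float
    mr_e: float
    d_e: float
    d_u: float
    d_attributed: float  # negative = deaths prevented

    @property
    def deaths_prevented(self) -> float:
        return -self.d_attributed


def attributable_deaths(
    rr_heat: float, mr_pop: float, p_e: float, pop: float
) -> AttributableDeaths:
    """Annual deaths attributable to the exposure in a population of ``pop``."""
    denom = 1.0 - p_e * (1.0 - rr_heat)
    if denom <= 0:
        raise PAError(f"non-positive attributable-risk denominator ({denom:g})")
    mr_u = mr_pop / denom
    mr_e = mr_pop * rr_heat / denom
    d_e = mr_e * pop
    d_u = mr_u * pop
    return AttributableDeaths(
        rr_heat=rr_heat, mr_u=mr_u, mr_e=mr_e, d_e=d_e, d_u=d_u, d_attributed=d_e - d_u
    )


class PAAssessmentInput(BaseModel):
    """One case (reference or comparison) of a physical-activity assessment."""

    mode: str
    at_heat: float = Field(ge=0, description="active travel, min/week")
    rr_lit: float = Field(gt=0, lt=1)
    at_lit: float = Field(gt=0, description="reference volume, min/week")
    cap: float = Field(gt=0, lt=1, description="maximum risk reduction")
    mr_pop: float = Field(gt=0, lt=1, description="deaths/person/year")
    p_e: float = Field(gt=0, le=1, description="exposed fraction")
    pop: float = Field(gt=0, description="persons assessed")

    @model_validator(mode="after")
    def _ok(self) -> "PAAssessmentInput":
        return self

    @classmethod
    def from_minutes_per_day(cls, minutes_per_day: float, **kw) -> "PAAssessmentInput":
        """Build from the standard daily unit (min/week = min/day × 7)."""
        return cls(at_heat=minutes_per_day * 7.0, **kw)

    def attributable(self, rr_adjustment: float = 1.0) -> AttributableDeaths:
        rr_lit = self.rr_lit * rr_adjustment
        rr = scale_rr(rr_lit, self.at_lit, self.at_heat, self.cap)
        return attributable_deaths(rr, self.mr_pop, self.p_e, self.pop)


def pa_impact(
    case_ref: PAAssessmentInput,
    case_comp: PAAssessmentInput,
    rr_adjustment: float = 1.0,
) -> float:
    """Steady-state annual deaths prevented by the travel contrast.

    Computed as D_attributed(reference) − D_attributed(comparison); positive
    when the comparison case has more active travel.  ``rr_adjustment``
    multiplies RR_lit when the air-pollution pathway is co-assessed (the
    literature risks were not adjusted for concurrent pollution exposure;
    the difference is negligible and the default is 1).
    """
    for f in ("mode", "pop", "mr_pop", "p_e"):
        if getattr(case_ref, f) != getattr(case_comp, f):
            raise PAError(f"reference and comparison cases differ in {f}")
    d_ref = case_ref.attributable(rr_adjustment).d_attributed
    d_comp = case_comp.attributable(rr_adjustment).d_attributed
    return d_ref - d_comp
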