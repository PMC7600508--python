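"""Volume adjustments applied between standardization and impact calculation.

Covers: excluding background-trend growth from the intervention contrast,
correcting count data for seasonal/geographic distortion, discounting active
travel that merely substitutes other physical activity (physical-activity
pathway only), the traffic/purpose splits feeding the air-pollution pathway,
and attributing kilometre contrasts to the motorized modes they replace for
the carbon pathway.
"""

from __future__ import annotations

from typing import Literal, Mapping

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .travel import StandardizedVolume

#: Categories a shifted active-travel kilometre can be attributed to.
SHIFT_CATEGORIES = (
    "new_trips",
    "reassigned_trips",
    "from_walking",
    "from_cycling",
    "from_car",
    "from_bus",
    "from_motorcycle",
    "from_other_motorized",
)
MOTORIZED_SHIFT = ("from_car", "from_bus", "from_motorcycle", "from_other_motorized")


class AdjustmentError(ValueError):
    pass


class ModeShift(BaseModel):
    """Where the assessed active-travel kilometres come from.

    ``new_trips`` (induced travel) and ``reassigned_trips`` (same mode, new
    route) replace no motorized travel.  Shares must sum to 1.  The defaults
    are deliberately round, urban-plausible values and should be replaced
    with local data whenever available.
    """

    model_config = ConfigDict(extra="forbid")

    new_trips: float = Field(default=0.1, ge=0, le=1)
    reassigned_trips: float = Field(default=0.1, ge=0, le=1)
    from_walking: float = Field(default=0.1, ge=0, le=1)
    from_cycling: float = Field(default=0.0, ge=0, le=1)
    from_car: float = Field(default=0.4, ge=0, le=1)
    from_bus: float = Field(default=0.3, ge=0, le=1)
    from_motorcycle: float = Field(default=0.0, ge=0, le=1)
    from_other_motorized: float = Field(default=0.0, ge=0, le=1)

    @model_validator(mode="after")
    def _sums_to_one(self) -> "ModeShift":
        total = sum(getattr(self, c) for c in SHIFT_CATEGORIES)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mode shift shares must sum to 1, got {total!r}")
        return self


class AdjustmentSet(BaseModel):
    """All optional volume adjustments; defaults are neutral."""

    model_config = ConfigDict(extra="forbid")

    #: Fraction of the reference→comparison growth attributed to a general
    #: trend rather than the assessed intervention (excluded from contrast).
    excluded_trend_fraction: float = Field(default=0.0, ge=0, le=1)
    #: Seasonal/geographic correction multiplier for count-based volumes.
    count_correction_factor: float = Field(default=1.0, ge=0)
    #: Fraction of active-travel minutes replacing other physical activity;
    #: reduces the physical-activity pathway's effective volume only.
    pa_substitution_fraction: float = Field(default=0.0, ge=0, le=1)
    #: Fraction of active travel taking place in elevated-pollution areas.
    prop_in_traffic: float = Field(default=1.0, ge=0, le=1)
    #: Fraction of active travel for transport (vs leisure) purposes.
    prop_transport_purpose: float = Field(default=1.0, ge=0, le=1)
    mode_shift: ModeShift = Field(default_factory=ModeShift)


Pathway = Literal["exposure", "physical_activity"]


def apply_volume_adjustments(
    vol: StandardizedVolume,
    adj: AdjustmentSet,
    *,
    reference: StandardizedVolume | None = None,
    pathway: Pathway = "exposure",
) -> StandardizedVolume:
    """Adjusted volume for one case.

    The count correction rescales the absolute level.  When ``reference`` is
    given, ``vol`` is treated as the comparison case and only the increment
    over the reference is kept at ``1 − excluded_trend_fraction`` of its
    size (trend exclusion applies to the intervention-attributable change,
    not to absolute levels).  For ``pathway="physical_activity"`` volumes are
    additionally scaled by ``1 − pa_substitution_fraction``; air-pollution,
    crash and carbon exposure accrue to the travel itself and stay unscaled.
    """
    out = vol.scaled(adj.count_correction_factor)
    if reference is not None:
        ref = reference.scaled(adj.count_correction_factor)
        keep = 1.0 - adj.excluded_trend_fraction
        out = out.model_copy(
            update={
                "minutes_per_person_day": ref.minutes_per_person_day
                + (out.minutes_per_person_day - ref.minutes_per_person_day) * keep,
                "km_per_person_day": ref.km_per_person_day
                + (out.km_per_person_day - ref.km_per_person_day) * keep,
            }
        )
    if pathway == "physical_activity":
        out = out.scaled(1.0 - adj.pa_substitution_fraction)
    return out


def attribute_mode_shift(km_contrast: float, shares: ModeShift) -> dict[str, float]:
    """Split a kilometre contrast across shift categories.

    Conservation holds exactly: the returned values sum to ``km_contrast``.
    Only the motorized categories represent avoided vehicle travel.
    """
    return {c: km_contrast * getattr(shares, c) for c in SHIFT_CATEGORIES}


def motorized_km(attributed: Mapping[str, float]) -> dict[str, float]:
    """Motorized person-km avoided, keyed by source mode (car/bus/...)."""
    return {c.removeprefix("from_"): attributed[c] for c in MOTORIZED_SHIFT}
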