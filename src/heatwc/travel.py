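"""Travel-volume standardization.

All downstream calculations run on two standard units — minutes per person
per day and kilometres per person per day.  This module converts any of the
supported input units (minutes, hours, kilometres, miles, trips, counts,
steps, frequency categories, mode share) into both standard units, using
overridable conversion defaults (average speed, trip distance, step length),
and carries the population context (size, type, age range) along.
"""

from __future__ import annotations

from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .registry import ACTIVE_MODES, CYCLING, WALKING

MILE_TO_KM = 1.609344

Unit = Literal[
    "minutes",
    "hours",
    "kilometers",
    "miles",
    "trips",
    "counts",
    "steps",
    "frequency_categories",
    "mode_share",
]

PopulationType = Literal["general_population", "active_travelers_only"]
AgeRange = Literal["young_adults", "average", "older_adults"]

#: Mortality-rate age band per (age range option, mode).  Cycling spans
#: 20–64, walking 20–74, because mortality in older ranges would dominate.
_AGE_KEY = {
    ("young_adults", WALKING): "20_44",
    ("young_adults", CYCLING): "20_44",
    ("average", WALKING): "20_74",
    ("average", CYCLING): "20_64",
    ("older_adults", WALKING): "45_74",
    ("older_adults", CYCLING): "45_64",
}


class TravelInputError(ValueError):
    """Raised for invalid or incomplete travel-volume inputs."""


class PopulationSpec(BaseModel):
    """Population the travel volumes refer to."""

    size: float = Field(gt=0, description="persons")
    type: PopulationType = "general_population"
    age_range: AgeRange = "average"

    def mortality_age_key(self, mode: str) -> str:
        """Registry age-band key for this population and mode."""
        return _AGE_KEY[(self.age_range, mode)]


class ConversionParams(BaseModel):
    """Defaults used to convert between input units (all user-overridable)."""

    speed_kmh: dict[str, float] = Field(
        default_factory=lambda: {WALKING: 5.3, CYCLING: 14.0},
        description="average travel speed, km/h",
    )
    trip_distance_km: dict[str, float] = Field(
        default_factory=lambda: {WALKING: 1.0, CYCLING: 3.0},
        description="average trip distance, km",
    )
    step_length_m: float = Field(default=0.7, gt=0)

    @model_validator(mode="after")
    def _positive(self) -> "ConversionParams":
        for d in (self.speed_kmh, self.trip_distance_km):
            if set(d) != set(ACTIVE_MODES):
                raise ValueError(f"per-mode params need keys {ACTIVE_MODES}")
            if any(v <= 0 for v in d.values()):
                raise ValueError("conversion parameters must be > 0")
        return self


class FrequencyCategory(BaseModel):
    """One row of a categorical mode-use-frequency survey question."""

    share_pct: float = Field(ge=0, le=100, description="% of population in category")
    days_per_week: float = Field(ge=0, le=7)
    minutes_per_active_day: float = Field(ge=0)


class RawTravelInput(BaseModel):
    """Travel volume in any supported unit, plus unit-specific extras."""

    model_config = ConfigDict(extra="forbid")

    mode: Literal["walking", "cycling"]
    unit: Unit
    value: Optional[float] = Field(default=None, ge=0)
    categories: Optional[list[FrequencyCategory]] = None
    #: mode_share only: total travel volume across all modes, per person/day.
    total_volume: Optional[float] = Field(default=None, ge=0)
    total_volume_unit: Optional[Literal["minutes", "kilometers", "trips"]] = None
    #: counts only: number of count locations and active-travel minutes each
    #: counted pass represents (defaults to one average trip's duration).
    n_locations: int = Field(default=1, ge=1)
    minutes_per_count: Optional[float] = Field(default=None, gt=0)

    @model_validator(mode="after")
    def _unit_specific(self) -> "RawTravelInput":
        if self.unit == "steps" and self.mode != WALKING:
            raise ValueError("steps input is only supported for walking")
        if self.unit == "frequency_categories":
            if not self.categories:
                raise ValueError("frequency_categories input requires a category table")
        elif self.value is None:
            raise ValueError(f"unit {self.unit!r} requires a numeric value")
        if self.unit == "mode_share":
            if self.value is not None and self.value > 100:
                raise ValueError("mode_share must be in [0, 100] %")
            if self.total_volume is None or self.total_volume_unit is None:
                raise ValueError("mode_share requires total_volume and total_volume_unit")
        return self


class StandardizedVolume(BaseModel):
    """Active travel in the two standard units with population context."""

    mode: Literal["walking", "cycling"]
    minutes_per_person_day: float = Field(ge=0)
    km_per_person_day: float = Field(ge=0)
    population: PopulationSpec

    def scaled(self, factor: float) -> "StandardizedVolume":
        """Both units scaled by a non-negative factor (same population)."""
        if factor < 0:
            raise ValueError("scale factor must be >= 0")
        return self.model_copy(
            update={
                "minutes_per_person_day": self.minutes_per_person_day * factor,
                "km_per_person_day": self.km_per_person_day * factor,
            }
        )


def frequency_to_minutes(categories: list[FrequencyCategory]) -> float:
    """Population-weighted minutes/person/day from a frequency-category table.

    Each category contributes share × days/7 × minutes per active day.
    Shares must sum to 100% (±0.1).
    """
    total = sum(c.share_pct for c in categories)
    if abs(total - 100.0) > 0.1:
        raise TravelInputError(f"category shares must sum to 100%, got {total:g}%")
    return sum(
        (c.share_pct / 100.0) * (c.days_per_week / 7.0) * c.minutes_per_active_day
        for c in categories
    )


def standardize(
    raw: RawTravelInput, pop: PopulationSpec, conv: ConversionParams | None = None
) -> StandardizedVolume:
    """Convert a raw travel input into minutes and km per person per day."""
    conv = conv or ConversionParams()
    speed = conv.speed_kmh[raw.mode]
    minutes: float | None = None
    km: float | None = None

    unit, value = raw.unit, raw.value
    if unit == "mode_share":
        # resolve the share into an absolute volume, then fall through
        value = (raw.value / 100.0) * raw.total_volume
        unit = raw.total_volume_unit

    if unit == "minutes":
        minutes = value
    elif unit == "hours":
        minutes = value * 60.0
    elif unit == "kilometers":
        km = value
    elif unit == "miles":
        km = value * MILE_TO_KM
    elif unit == "trips":
        km = value * conv.trip_distance_km[raw.mode]
    elif unit == "steps":
        km = value * conv.step_length_m / 1000.0
    elif unit == "counts":
        per_count = (
            raw.minutes_per_count
            if raw.minutes_per_count is not None
            else conv.trip_distance_km[raw.mode] / speed * 60.0
        )
        minutes = value * raw.n_locations * per_count / pop.size
    elif unit == "frequency_categories":
        minutes = frequency_to_minutes(raw.categories)
    else:  # pragma: no cover - Unit literal is exhaustive
        raise TravelInputError(f"unsupported unit {unit!r}")

    if minutes is None:
        minutes = km / speed * 60.0
    if km is None:
        km = minutes / 60.0 * speed
    return StandardizedVolume(
        mode=raw.mode,
        minutes_per_person_day=minutes,
        km_per_person_day=km,
        population=pop,
    )


def zero_volume(mode: str, pop: PopulationSpec) -> StandardizedVolume:
    """A no-travel volume (the comparison case of a single-case assessment)."""
    return StandardizedVolume(
        mode=mode, minutes_per_person_day=0.0, km_per_person_day=0.0, population=pop
    )
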