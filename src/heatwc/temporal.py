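"""Per-year schedules: uptake, health-effect build-up, crash-risk change,
and economic discounting.

The assessment spans years k = 1..N.  Year k maps to the calendar year
``reference_year + k`` and impacts are attributed at year-end, which makes
discount exponents unambiguous.

Temporal model
--------------
* *Uptake*: the travel contrast grows linearly from the reference level and
  reaches the comparison level in year u (step change for u = 0).
* *Build-up*: achieved travel volumes need time to develop their full
  mortality effect.  The realized health effect ramps linearly from zero to
  the full steady-state impact over ``uptake + buildup`` years, so a 5-year
  uptake followed by the default 5-year build-up first yields the full
  annual impact in year 10; a step change (u = 0) reaches it in year b.
* *Crash-risk change*: a user-specified relative change in the fatality
  rate is interpolated linearly from year 1 to year N.
* *Discounting*: monetary values in year k are divided by
  ``(1 + r)^(calendar_year(k) − discount_year)``; values before the
  discount year are inflated.

Uptake and build-up do not apply to single-case (steady-state) assessments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from pydantic import BaseModel, Field, model_validator


class TimeFrame(BaseModel):
    """Assessment period and temporal parameters."""

    reference_year: int = 2020
    assessment_years: int = Field(default=10, ge=1)
    uptake_years: int = Field(default=1, ge=0)
    buildup_years: int = Field(default=5, ge=0)
    discount_rate: float = Field(default=0.05, ge=0, description="per year")
    discount_year: int | None = Field(
        default=None, description="defaults to the reference year"
    )

    @model_validator(mode="after")
    def _default_discount_year(self) -> "TimeFrame":
        if self.discount_year is None:
            object.__setattr__(self, "discount_year", self.reference_year)
        return self

    @property
    def years(self) -> np.ndarray:
        """Calendar years of the assessment (year k = reference_year + k)."""
        return self.reference_year + 1 + np.arange(self.assessment_years)

    def steady_state(self) -> "TimeFrame":
        """Copy with uptake and build-up zeroed (single-case assessments)."""
        return self.model_copy(update={"uptake_years": 0, "buildup_years": 0})


@dataclass
class YearSeries:
    """A value for each assessment year k = 1..N.

    ``start_year`` is the calendar year of k = 1.
    """

    start_year: int
    values: np.ndarray = field()

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError("YearSeries needs a 1-D array with >= 1 year")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def years(self) -> np.ndarray:
        return self.start_year + np.arange(self.n)

    def total(self) -> float:
        return float(self.values.sum())

    def mean(self) -> float:
        return float(self.values.mean())

    def map(self, fn) -> "YearSeries":
        return YearSeries(self.start_year, fn(self.values))

    def __mul__(self, other: float) -> "YearSeries":
        return YearSeries(self.start_year, self.values * float(other))

    __rmul__ = __mul__

    def __add__(self, other: "YearSeries") -> "YearSeries":
        if not isinstance(other, YearSeries):
            return NotImplemented
        if other.start_year != self.start_year or other.n != self.n:
            raise ValueError("cannot add YearSeries over different periods")
        return YearSeries(self.start_year, self.values + other.values)

    def to_records(self) -> list[dict]:
        return [
            {"year": int(y), "value": float(v)} for y, v in zip(self.years, self.values)
        ]


def _k(tf: TimeFrame) -> np.ndarray:
    return np.arange(1, tf.assessment_years + 1, dtype=float)


def uptake_series(ref_level: float, comp_level: float, tf: TimeFrame) -> YearSeries:
    """Travel level per year, interpolating reference→comparison over uptake.

    value(k) = ref + (comp − ref) × min(k/u, 1); u = 0 gives the comparison
    level from year 1.
    """
    k = _k(tf)
    frac = np.minimum(k / tf.uptake_years, 1.0) if tf.uptake_years > 0 else np.ones_like(k)
    return YearSeries(tf.reference_year + 1, ref_level + (comp_level - ref_level) * frac)


def effect_fraction(tf: TimeFrame) -> YearSeries:
    """Fraction of the full steady-state health impact realized in each year.

    min(k / (uptake + buildup), 1); identically 1 when both are zero.
    """
    k = _k(tf)
    span = tf.uptake_years + tf.buildup_years
    frac = np.minimum(k / span, 1.0) if span > 0 else np.ones_like(k)
    return YearSeries(tf.reference_year + 1, frac)


def buildup_series(
    contrast: YearSeries,
    buildup_years: int,
    uptake_years: int = 0,
    full_contrast: float | None = None,
) -> YearSeries:
    """Health-effective contrast: full contrast × the linear build-up ramp.

    The realized effect rises linearly and first equals the full travel
    contrast in year ``uptake_years + buildup_years`` (identity when both
    are zero).  ``full_contrast`` defaults to the final value of
    ``contrast``; pass it explicitly when the assessment horizon ends
    before the uptake completes.
    """
    if buildup_years < 0 or uptake_years < 0:
        raise ValueError("build-up and uptake years must be >= 0")
    span = uptake_years + buildup_years
    if span == 0:
        return YearSeries(contrast.start_year, contrast.values.copy())
    k = np.arange(1, contrast.n + 1, dtype=float)
    full = contrast.values[-1] if full_contrast is None else full_contrast
    return YearSeries(contrast.start_year, full * np.minimum(k / span, 1.0))


def crash_risk_series(rate_ref: float, rate_comp: float, tf: TimeFrame) -> YearSeries:
    """Fatality rate per year, linear from rate_ref (year 1) to rate_comp (year N)."""
    if rate_ref < 0 or rate_comp < 0:
        raise ValueError("crash rates must be >= 0")
    n = tf.assessment_years
    if n == 1:
        vals = np.array([rate_comp], dtype=float)
    else:
        vals = rate_ref + (rate_comp - rate_ref) * (np.arange(n) / (n - 1))
    return YearSeries(tf.reference_year + 1, vals)


def discount_series(values: YearSeries, tf: TimeFrame) -> YearSeries:
    """Present value of a monetary series at the discount year.

    pv(k) = value(k) / (1 + r)^(calendar_year(k) − discount_year); years
    before the discount year are inflated.
    """
    if tf.discount_rate < 0:
        raise ValueError("discount rate must be >= 0")
    exponent = values.years - tf.discount_year
    return YearSeries(values.start_year, values.values / (1.0 + tf.discount_rate) ** exponent)
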