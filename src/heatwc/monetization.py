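"""Monetization: country-specific VSL, SCC valuation, discounting,
aggregation and benefit–cost ratios.

The value of statistical life transfers an OECD-average 2005 base value to
a country and to 2015 prices with an income-elasticity adjustment:

    VSL_country,2015 (local currency)
        = VSL_OECD,2005,USD × (Y_country,2005 / Y_OECD,2005)^IE
          × PPP_2005 × (1 + %ΔP_2005–2015) × (1 + %ΔY_2005–2015)^IE

with base value USD 3.013 million, OECD-average GDP/capita at PPP of
USD 30,801 (2005) and income elasticity 0.8.  Deaths prevented enter with
positive value, deaths caused (air pollution, crashes) with negative
value.  Avoided carbon is valued per emission year with the social cost of
carbon schedule; because the SCC is a global damage value in USD_2015
while the VSL lands in local currency, the carbon subtotal is kept
separate from the health subtotal before combination.  All value series
are discounted to the assessment's discount year; the benefit–cost ratio
divides the combined net discounted value by the investment cost.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from pydantic import BaseModel, Field

from .registry import SCCSchedule, VSLInputs, default_scc
from .temporal import TimeFrame, YearSeries, discount_series

#: OECD meta-analytic base VSL (USD, 2005 prices).
VSL_BASE_OECD_2005_USD = 3.013e6
#: OECD-average real GDP per capita at PPP, 2005 USD.
Y_OECD_2005 = 30801.0
#: Income elasticity of the VSL.
INCOME_ELASTICITY = 0.8


class VSLParams(BaseModel):
    """Inputs to the VSL benefit transfer."""

    vsl_base_oecd_2005: float = Field(default=VSL_BASE_OECD_2005_USD, gt=0, description="USD")
    y_country_2005: float = Field(gt=0, description="GDP/capita at PPP, 2005 USD")
    y_oecd_2005: float = Field(default=Y_OECD_2005, gt=0)
    income_elasticity: float = Field(default=INCOME_ELASTICITY, ge=0, le=2)
    ppp_2005: float = Field(gt=0, description="local currency per USD")
    inflation_2005_2015: float = Field(ge=-0.99)
    income_growth_2005_2015: float = Field(ge=-0.99)

    @classmethod
    def from_country(cls, inputs: VSLInputs, **overrides) -> "VSLParams":
        return cls(
            y_country_2005=inputs.gdp_pc_2005_ppp,
            ppp_2005=inputs.ppp_2005,
            inflation_2005_2015=inputs.inflation_2005_2015,
            income_growth_2005_2015=inputs.income_growth_2005_2015,
            **overrides,
        )


def derive_vsl(p: VSLParams) -> float:
    """Country VSL in local currency at 2015 prices."""
    ie = p.income_elasticity
    return (
        p.vsl_base_oecd_2005
        * (p.y_country_2005 / p.y_oecd_2005) ** ie
        * p.ppp_2005
        * (1.0 + p.inflation_2005_2015)
        * (1.0 + p.income_growth_2005_2015) ** ie
    )


def value_health(deaths_series: YearSeries, vsl: float) -> YearSeries:
    """Monetary value of a signed deaths-prevented series.

    Pass deaths *prevented* with positive sign and deaths *caused* (air
    pollution, crash) with negative sign; harms then carry negative value.
    """
    if vsl <= 0:
        raise ValueError("VSL must be > 0")
    return deaths_series * vsl


def value_carbon(tonnes_series: YearSeries, scc: SCCSchedule) -> YearSeries:
    """Value avoided tonnes at the SCC of their emission year (USD_2015)."""
    vals = [
        t * default_scc(scc, int(y)) for t, y in zip(tonnes_series.values, tonnes_series.years)
    ]
    return YearSeries(tonnes_series.start_year, vals)


@dataclass
class PathwayValue:
    """One mode × pathway component prior to aggregation."""

    mode: str
    pathway: str
    #: physical quantity per year: deaths prevented (+) / caused (−), or
    #: tonnes CO2e avoided for the carbon pathway
    quantity: YearSeries
    #: signed monetary value per year (benefit positive), undiscounted
    value: YearSeries


@dataclass
class AggregatedComponent:
    mode: str
    pathway: str
    quantity: YearSeries
    value: YearSeries
    discounted: YearSeries
    total_quantity: float = field(init=False)
    total_value: float = field(init=False)
    annual_mean_value: float = field(init=False)

    def __post_init__(self) -> None:
        self.total_quantity = self.quantity.total()
        self.total_value = self.discounted.total()
        self.annual_mean_value = self.discounted.mean()


@dataclass
class MonetizedResult:
    """Discounted values by mode × pathway, with totals and optional BCR."""

    components: list[AggregatedComponent]
    timeframe: TimeFrame
    health_currency: str
    carbon_currency: str = "USD_2015"
    investment_cost: Optional[float] = None

    def _total(self, pred) -> float:
        return sum(c.total_value for c in self.components if pred(c))

    @property
    def total_by_mode(self) -> dict[str, float]:
        modes = sorted({c.mode for c in self.components})
        return {m: self._total(lambda c, m=m: c.mode == m) for m in modes}

    @property
    def total_by_pathway(self) -> dict[str, float]:
        pws = sorted({c.pathway for c in self.components})
        return {p: self._total(lambda c, p=p: c.pathway == p) for p in pws}

    @property
    def health_total(self) -> float:
        return self._total(lambda c: c.pathway != "carbon")

    @property
    def carbon_total(self) -> float:
        return self._total(lambda c: c.pathway == "carbon")

    @property
    def combined_total(self) -> float:
        return sum(c.total_value for c in self.components)

    @property
    def combined_annual_mean(self) -> float:
        return self.combined_total / self.timeframe.assessment_years

    @property
    def benefit_cost_ratio(self) -> Optional[float]:
        """Net discounted benefit over investment cost; absent without a cost."""
        if self.investment_cost is None or self.investment_cost <= 0:
            return None
        return self.combined_total / self.investment_cost


def aggregate(
    components: Sequence[PathwayValue],
    tf: TimeFrame,
    investment_cost: Optional[float] = None,
    health_currency: str = "USD",
) -> MonetizedResult:
    """Discount every component and assemble totals.

    All series must share the assessment period; aggregation is exactly
    additive and permutation-invariant.
    """
    aggregated = []
    for comp in components:
        for s in (comp.quantity, comp.value):
            if s.start_year != tf.reference_year + 1 or s.n != tf.assessment_years:
                raise ValueError(
                    f"{comp.mode}/{comp.pathway}: series period does not match the time frame"
                )
        aggregated.append(
            AggregatedComponent(
                mode=comp.mode,
                pathway=comp.pathway,
                quantity=comp.quantity,
                value=comp.value,
                discounted=discount_series(comp.value, tf),
            )
        )
    return MonetizedResult(
        components=aggregated,
        timeframe=tf,
        health_currency=health_currency,
        investment_cost=investment_cost,
    )
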