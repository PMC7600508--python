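"""Assessment engine: orchestrates a full run from a declarative config.

A single configuration object (typically loaded from YAML) defines the use
case — modes, geography, single- vs two-case comparison, time frame,
pathways, travel inputs, adjustments, population and monetization options.
``validate`` checks every use-case rule and reports *all* violations;
``run_assessment`` executes the validated plan deterministically and
returns monetized results plus a full audit trail of intermediates.

Use-case rules enforced here:

* count data only at the sub-city scale (area extrapolation from counts is
  not supported);
* the crash pathway only for cycling, only for countries with a fatality
  rate, and never at the sub-city scale;
* single-case assessments are steady states: uptake and build-up are
  forced to zero and the comparison is the zero-travel case internally, so
  the reported impact is the benefit of the assessed volumes.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import __version__ as _pkg_version
from .adjustments import (
    AdjustmentSet,
    apply_volume_adjustments,
    attribute_mode_shift,
    motorized_km,
)
from .air_pollution import (
    APConstants,
    APExposureInput,
    ap_impact,
    case_rr,
    equivalent_excess_concentration,
)
from .carbon import CarbonParams, TrafficCondition, carbon_avoided, carbon_impact
from .crash import CrashInput, crash_impact
from .monetization import (
    MonetizedResult,
    PathwayValue,
    VSLParams,
    aggregate,
    derive_vsl,
    value_carbon,
    value_health,
)
from .physical_activity import PAAssessmentInput, pa_impact
from .registry import CYCLING, WALKING, ParameterRegistry
from .temporal import TimeFrame, YearSeries, effect_fraction
from .travel import (
    ConversionParams,
    PopulationSpec,
    RawTravelInput,
    StandardizedVolume,
    standardize,
    zero_volume,
)

PATHWAYS = ("physical_activity", "air_pollution", "crash", "carbon")
Scale = Literal["country", "city", "sub_city"]


class AssessmentValidationError(ValueError):
    """Aggregated use-case rule violations (never first-failure-only)."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid assessment configuration:\n- " + "\n- ".join(errors))


class ModeTravelConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    reference: RawTravelInput
    comparison: Optional[RawTravelInput] = None


class CrashConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    #: Fractional change in crash risk reference→comparison (e.g. −0.3).
    risk_change: float = Field(default=0.0, ge=-1)
    #: Local override of the registry fatality rate (per 100 million km).
    fatality_rate_override: Optional[float] = Field(default=None, ge=0)


class CarbonConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    traffic_condition: TrafficCondition = "urban"
    detour_factor: float = Field(default=1.0, gt=0)
    active_mode_ef: float = Field(default=0.0, ge=0)


class MonetizationConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    investment_cost: Optional[float] = Field(default=None, gt=0)
    vsl_override: Optional[float] = Field(default=None, gt=0)


class AssessmentConfig(BaseModel):
    """Declarative description of one assessment."""

    model_config = ConfigDict(extra="forbid")

    country: str
    city: Optional[str] = None
    scale: Scale = "country"
    comparison: Literal["single_case", "two_case"] = "single_case"
    modes: list[Literal["walking", "cycling"]]
    pathways: list[Literal["physical_activity", "air_pollution", "crash", "carbon"]]
    timeframe: TimeFrame = Field(default_factory=TimeFrame)
    population: PopulationSpec
    travel: dict[str, ModeTravelConfig]
    adjustments: AdjustmentSet = Field(default_factory=AdjustmentSet)
    conversion: ConversionParams = Field(default_factory=ConversionParams)
    crash: CrashConfig = Field(default_factory=CrashConfig)
    carbon: CarbonConfig = Field(default_factory=CarbonConfig)
    monetization: MonetizationConfig = Field(default_factory=MonetizationConfig)

    @classmethod
    def from_dict(cls, data: dict) -> "AssessmentConfig":
        try:
            return cls(**data)
        except ValidationError as exc:
            errors = [
                ".".join(str(p) for p in e["loc"]) + ": " + e["msg"] for e in exc.errors()
            ]
            raise AssessmentValidationError(errors) from None


def validate(config: AssessmentConfig, registry: ParameterRegistry) -> list[str]:
    """Check every use-case rule; return the full list of violations."""
    errors: list[str] = []
    if config.country not in registry.countries:
        errors.append(f"unknown country {config.country!r}")
    if not config.modes:
        errors.append("at least one active mode must be assessed")
    if len(set(config.modes)) != len(config.modes):
        errors.append("modes must be unique")
    if not config.pathways:
        errors.append("at least one pathway must be assessed")

    for mode in config.modes:
        if mode not in config.travel:
            errors.append(f"no travel input for mode {mode!r}")
            continue
        block = config.travel[mode]
        if block.reference.mode != mode:
            errors.append(f"travel.{mode}.reference declares mode {block.reference.mode!r}")
        if config.comparison == "two_case" and block.comparison is None:
            errors.append(f"two-case assessment needs travel.{mode}.comparison")
        if config.comparison == "single_case" and block.comparison is not None:
            errors.append(
                f"single-case assessment takes only travel.{mode}.reference "
                "(the comparison is the zero-travel case)"
            )
        for case_name, case in (("reference", block.reference), ("comparison", block.comparison)):
            if case is None:
                continue
            if case.unit == "counts" and config.scale != "sub_city":
                errors.append(
                    f"travel.{mode}.{case_name}: count data can only be used for "
                    "sub-city assessments"
                )

    if "crash" in config.pathways:
        if CYCLING not in config.modes:
            errors.append(
                "crash pathway is available for cycling only "
                "(pedestrian crash rates are not provided)"
            )
        if config.scale == "sub_city":
            errors.append("crash risk assessments are not supported at the sub-city scale")
        if (
            config.country in registry.countries
            and config.crash.fatality_rate_override is None
            and registry.countries[config.country].cycling_fatality_rate is None
        ):
            errors.append(
                f"no cycling fatality rate for country {config.country!r}; "
                "the crash pathway is only offered for selected countries "
                "(or provide crash.fatality_rate_override)"
            )
    if "carbon" in config.pathways and config.country in registry.countries:
        if not registry.countries[config.country].emission_factors:
            errors.append(f"no emission factors for country {config.country!r}")
    return errors


@dataclass
class PathwayOutput:
    """Per-year physical impact of one mode × pathway."""

    mode: str
    pathway: str
    #: "deaths_prevented", "deaths_caused" or "tonnes_co2e_avoided"
    quantity_kind: str
    series: YearSeries


@dataclass
class AssessmentResult:
    """Everything a run produces: impacts, money, and the audit trail."""

    config: AssessmentConfig
    timeframe: TimeFrame
    impacts: list[PathwayOutput]
    monetized: MonetizedResult
    vsl_local: float
    audit: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            "engine_version": _pkg_version,
            "country": self.config.country,
            "comparison": self.config.comparison,
            "timeframe": {
                "reference_year": self.timeframe.reference_year,
                "assessment_years": self.timeframe.assessment_years,
                "uptake_years": self.timeframe.uptake_years,
                "buildup_years": self.timeframe.buildup_years,
                "discount_rate": self.timeframe.discount_rate,
                "discount_year": self.timeframe.discount_year,
            },
            "vsl_local_2015": self.vsl_local,
            "health_currency": self.monetized.health_currency,
            "carbon_currency": self.monetized.carbon_currency,
            "impacts": [
                {
                    "mode": p.mode,
                    "pathway": p.pathway,
                    "quantity": p.quantity_kind,
                    "annual": p.series.to_records(),
                    "total": p.series.total(),
                }
                for p in self.impacts
            ],
            "values": [
                {
                    "mode": c.mode,
                    "pathway": c.pathway,
                    "discounted_annual": c.discounted.to_records(),
                    "total_value": c.total_value,
                    "annual_mean_value": c.annual_mean_value,
                }
                for c in self.monetized.components
            ],
            "totals": {
                "by_mode": self.monetized.total_by_mode,
                "by_pathway": self.monetized.total_by_pathway,
                "health": self.monetized.health_total,
                "carbon": self.monetized.carbon_total,
                "combined": self.monetized.combined_total,
                "combined_annual_mean": self.monetized.combined_annual_mean,
            },
            "audit": self.audit,
        }
        bcr = self.monetized.benefit_cost_ratio
        if bcr is not None:
            out["totals"]["benefit_cost_ratio"] = bcr
        return out

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)


def _checksum(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def _standardized_cases(
    config: AssessmentConfig, mode: str
) -> tuple[StandardizedVolume, StandardizedVolume]:
    """Reference and comparison volumes after standardization + adjustments.

    Single-case: internally the reference is zero travel and the assessed
    volumes are the comparison, so impact = comparison − reference equals
    the steady-state effect of current travel.
    """
    block = config.travel[mode]
    pop = config.population
    observed = standardize(block.reference, pop, config.conversion)
    adj = config.adjustments
    if config.comparison == "single_case":
        ref = zero_volume(mode, pop)
        comp = apply_volume_adjustments(observed, adj)
        return ref, comp
    ref = apply_volume_adjustments(observed, adj)
    comp_raw = standardize(block.comparison, pop, config.conversion)
    comp = apply_volume_adjustments(comp_raw, adj, reference=observed)
    return ref, comp


def run_assessment(
    config: AssessmentConfig, registry: ParameterRegistry
) -> AssessmentResult:
    """Run a validated assessment end-to-end (deterministic)."""
    errors = validate(config, registry)
    if errors:
        raise AssessmentValidationError(errors)

    constants = registry.constants
    country = registry.country(config.country)
    tf = config.timeframe
    if config.comparison == "single_case":
        tf = tf.steady_state()
    pop = config.population
    p_e = constants.p_exposed_default if pop.type == "general_population" else 1.0
    adj = config.adjustments

    eff = effect_fraction(tf)
    impacts: list[PathwayOutput] = []
    values: list[PathwayValue] = []
    vsl = (
        config.monetization.vsl_override
        if config.monetization.vsl_override is not None
        else derive_vsl(VSLParams.from_country(country.vsl_inputs))
    )
    scc = registry.scc_for(config.country)
    audit: dict = {
        "registry_checksum": _checksum(registry.model_dump(mode="json")),
        "config_checksum": _checksum(config.model_dump(mode="json")),
        "p_e": p_e,
        "vsl_local_2015": vsl,
        "modes": {},
    }

    for mode in config.modes:
        ref, comp = _standardized_cases(config, mode)
        mr_pop = country.mortality_rate[pop.mortality_age_key(mode)]
        mode_audit: dict = {
            "reference_volume": ref.model_dump(),
            "comparison_volume": comp.model_dump(),
            "mr_pop": mr_pop,
        }

        if "physical_activity" in config.pathways:
            ref_pa = apply_volume_adjustments(ref, adj, pathway="physical_activity")
            comp_pa = apply_volume_adjustments(comp, adj, pathway="physical_activity")
            rr_adj = (
                constants.pa_rr_ap_adjustment
                if "air_pollution" in config.pathways
                else 1.0
            )
            common = dict(
                mode=mode,
                rr_lit=constants.rr_lit[mode],
                at_lit=constants.at_lit[mode],
                cap=constants.cap[mode],
                mr_pop=mr_pop,
                p_e=p_e,
                pop=pop.size,
            )
            case_ref = PAAssessmentInput.from_minutes_per_day(
                ref_pa.minutes_per_person_day, **common
            )
            case_comp = PAAssessmentInput.from_minutes_per_day(
                comp_pa.minutes_per_person_day, **common
            )
            steady = pa_impact(case_ref, case_comp, rr_adj)
            series = eff * steady
            impacts.append(PathwayOutput(mode, "physical_activity", "deaths_prevented", series))
            values.append(
                PathwayValue(mode, "physical_activity", series, value_health(series, vsl))
            )
            mode_audit["physical_activity"] = {
                "rr_reference": case_ref.attributable(rr_adj).rr_heat,
                "rr_comparison": case_comp.attributable(rr_adj).rr_heat,
                "steady_deaths_prevented_per_year": steady,
            }

        if "air_pollution" in config.pathways:
            ap_const = APConstants(
                ventilation_active=constants.ventilation_active[mode],
                ventilation_rest=constants.ventilation_rest,
                daily_ventilation=constants.daily_ventilation,
                traffic_factor=constants.traffic_factor[mode],
                counterfactual_traffic_factor=constants.counterfactual_traffic_factor,
                rr_ap_per_10=constants.rr_ap_per_10,
            )

            def ap_case(vol: StandardizedVolume) -> APExposureInput:
                return APExposureInput(
                    mode=mode,
                    minutes_per_day=vol.minutes_per_person_day,
                    pm25_background=country.pm25_background,
                    prop_in_traffic=adj.prop_in_traffic,
                    prop_transport_purpose=adj.prop_transport_purpose,
                    constants=ap_const,
                )

            ap_ref, ap_comp = ap_case(ref), ap_case(comp)
            steady = ap_impact(ap_ref, ap_comp, mr_pop, p_e, pop.size)
            series = eff * steady
            impacts.append(PathwayOutput(mode, "air_pollution", "deaths_caused", series))
            values.append(
                PathwayValue(mode, "air_pollution", series, value_health(series * -1.0, vsl))
            )
            mode_audit["air_pollution"] = {
                "delta_c_reference": equivalent_excess_concentration(ap_ref),
                "delta_c_comparison": equivalent_excess_concentration(ap_comp),
                "rr_reference": case_rr(ap_ref),
                "rr_comparison": case_rr(ap_comp),
                "steady_deaths_caused_per_year": steady,
            }

        if "crash" in config.pathways and mode == CYCLING:
            rate = (
                config.crash.fatality_rate_override
                if config.crash.fatality_rate_override is not None
                else country.cycling_fatality_rate
            )
            crash_ref = CrashInput(
                mode=mode,
                km_per_person_day=ref.km_per_person_day,
                pop=pop.size,
                fatality_rate=rate,
            )
            crash_comp = crash_ref.model_copy(
                update={
                    "km_per_person_day": comp.km_per_person_day,
                    "risk_change": config.crash.risk_change,
                }
            )
            series = crash_impact(crash_ref, crash_comp, tf)
            impacts.append(PathwayOutput(mode, "crash", "deaths_caused", series))
            values.append(PathwayValue(mode, "crash", series, value_health(series * -1.0, vsl)))
            mode_audit["crash"] = {
                "fatality_rate_per_100Mkm": rate,
                "risk_change": config.crash.risk_change,
                "total_deaths_caused": series.total(),
            }

        if "carbon" in config.pathways:
            params = CarbonParams(
                factors=country.emission_factors,
                active_mode_ef=config.carbon.active_mode_ef,
                detour_factor=config.carbon.detour_factor,
                traffic_condition=config.carbon.traffic_condition,
            )

            def steady_tonnes(vol: StandardizedVolume) -> float:
                shifted = motorized_km(
                    attribute_mode_shift(vol.km_per_person_day * pop.size, adj.mode_shift)
                )
                return carbon_avoided(shifted, params)

            t_ref, t_comp = steady_tonnes(ref), steady_tonnes(comp)
            series = carbon_impact(t_ref, t_comp, tf)
            impacts.append(PathwayOutput(mode, "carbon", "tonnes_co2e_avoided", series))
            values.append(PathwayValue(mode, "carbon", series, value_carbon(series, scc)))
            mode_audit["carbon"] = {
                "steady_tonnes_reference": t_ref,
                "steady_tonnes_comparison": t_comp,
                "total_tonnes_avoided": series.total(),
            }

        audit["modes"][mode] = mode_audit

    monetized = aggregate(
        values,
        tf,
        investment_cost=config.monetization.investment_cost,
        health_currency=country.currency,
    )
    return AssessmentResult(
        config=config,
        timeframe=tf,
        impacts=impacts,
        monetized=monetized,
        vsl_local=vsl,
        audit=audit,
    )
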