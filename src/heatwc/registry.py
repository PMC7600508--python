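"""Background parameter registry.

Every science constant and country default the assessment engine needs lives
here: dose–response anchors for the physical-activity relative risk, exposure
constants for the air-pollution pathway, per-country mortality rates, ambient
PM2.5 levels, cycling fatality rates, value-of-statistical-life inputs,
emission factors, and the social-cost-of-carbon schedule.

Two plain CSV files back the registry (``constants.csv`` as key/mode/value
rows, ``countries.csv`` as one row per country), optionally layered with a
YAML override file.  A deterministic fixture generator emulates the WHO
background databases with synthetic countries so the engine is fully
self-contained.

Several defaults are not primary literature values but operational defaults
taken over from the tool's methodological guidance (flagged ``user-guide
derived`` in field docs): the relative-risk anchors ``rr_lit``/``at_lit``,
the PM2.5 mortality response ``rr_ap_per_10``, the resting and daily
ventilation volumes, and the in-vehicle (counterfactual) traffic factor.
All are plain registry entries and can be overridden per assessment.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

WALKING = "walking"
CYCLING = "cycling"
ACTIVE_MODES = (WALKING, CYCLING)
MOTORIZED_MODES = ("car", "bus", "motorcycle")

#: Age ranges with country mortality rates: young adults, older adults
#: (per-mode upper bound) and the mode-specific "average" ranges.
AGE_RANGES = ("20_44", "45_64", "45_74", "20_64", "20_74")


class RegistryError(ValueError):
    """Raised when a registry file violates the documented schema."""


def _per_mode(walking: float, cycling: float) -> dict[str, float]:
    return {WALKING: walking, CYCLING: cycling}


class ScienceConstants(BaseModel):
    """Hard-coded science constants of the assessment engine.

    Per-mode entries are keyed ``walking`` / ``cycling``.
    """

    model_config = ConfigDict(validate_assignment=True)

    #: All-cause mortality relative risk at the reference travel volume
    #: (user-guide derived, configurable).
    rr_lit: dict[str, float] = Field(default_factory=lambda: _per_mode(0.90, 0.90))
    #: Reference active-travel volume for rr_lit, min/week (user-guide derived).
    at_lit: dict[str, float] = Field(default_factory=lambda: _per_mode(168.0, 100.0))
    #: Maximum risk reduction of the linear dose–response (fraction).
    cap: dict[str, float] = Field(default_factory=lambda: _per_mode(0.30, 0.45))
    #: Ventilation while travelling actively, m³/hour.
    ventilation_active: dict[str, float] = Field(
        default_factory=lambda: _per_mode(1.37, 2.55)
    )
    #: Ventilation at rest, m³/hour (user-guide derived).
    ventilation_rest: float = 0.61
    #: Total daily ventilation volume, m³/day (user-guide derived).
    daily_ventilation: float = 16.0
    #: Multiplier on background PM2.5 while travelling in traffic.
    traffic_factor: dict[str, float] = Field(default_factory=lambda: _per_mode(1.6, 2.0))
    #: Multiplier on background PM2.5 for the counterfactual (in-vehicle)
    #: transport time replaced by active travel (user-guide derived).
    counterfactual_traffic_factor: float = 2.5
    #: All-cause mortality relative risk per 10 µg/m³ long-term PM2.5
    #: (user-guide derived, configurable).
    rr_ap_per_10: float = 1.07
    #: Multiplicative adjustment on the PA relative risk when the air
    #: pollution pathway is co-assessed (differences are negligible).
    pa_rr_ap_adjustment: float = 1.0
    #: Default exposed fraction of the general population.
    p_exposed_default: float = 0.001
    #: Years over which achieved travel volumes develop full health impact.
    buildup_years_default: int = 5
    #: Default years to reach the full travel contrast after an intervention.
    uptake_years_default: int = 1

    @field_validator("rr_lit", "at_lit", "cap", "ventilation_active", "traffic_factor")
    @classmethod
    def _modes_complete(cls, v: dict[str, float], info) -> dict[str, float]:
        if set(v) != set(ACTIVE_MODES):
            raise ValueError(f"{info.field_name} must have keys {ACTIVE_MODES}, got {sorted(v)}")
        return v

    @model_validator(mode="after")
    def _invariants(self) -> "ScienceConstants":
        for m in ACTIVE_MODES:
            if not 0 < self.rr_lit[m] < 1:
                raise ValueError(f"rr_lit[{m}] must be in (0,1)")
            if self.at_lit[m] <= 0:
                raise ValueError(f"at_lit[{m}] must be > 0")
            if not 0 < self.cap[m] < 1:
                raise ValueError(f"cap[{m}] must be in (0,1)")
            if self.ventilation_active[m] <= 0:
                raise ValueError(f"ventilation_active[{m}] must be > 0")
            if self.traffic_factor[m] < 1:
                raise ValueError(f"traffic_factor[{m}] must be >= 1")
        if self.ventilation_rest <= 0 or self.daily_ventilation <= 0:
            raise ValueError("ventilation rates must be > 0")
        if self.counterfactual_traffic_factor < 1:
            raise ValueError("counterfactual_traffic_factor must be >= 1")
        if self.rr_ap_per_10 < 1:
            raise ValueError("rr_ap_per_10 must be >= 1")
        if not 0 < self.p_exposed_default <= 1:
            raise ValueError("p_exposed_default must be in (0,1]")
        if self.buildup_years_default < 0 or self.uptake_years_default < 0:
            raise ValueError("temporal defaults must be >= 0")
        return self


class VSLInputs(BaseModel):
    """Country inputs for the value-of-statistical-life derivation."""

    gdp_pc_2005_ppp: float = Field(gt=0, description="real GDP/capita at PPP, 2005 USD")
    ppp_2005: float = Field(gt=0, description="local currency per USD at PPP, 2005")
    inflation_2005_2015: float = Field(ge=-0.99, description="CPI change 2005–2015, fraction")
    income_growth_2005_2015: float = Field(ge=-0.99, description="real GDP/capita growth 2005–2015, fraction")


class ModeEmissionFactors(BaseModel):
    """Per-vehicle-km CO2e emission factors and occupancy of a motorized mode."""

    ef_operational: float = Field(ge=0, description="in-use emissions, g CO2e/vehicle-km")
    ef_fuel_supply: float = Field(ge=0, description="fuel/energy supply emissions, g CO2e/vehicle-km")
    ef_lifecycle: float = Field(ge=0, description="vehicle life-cycle emissions, g CO2e/vehicle-km")
    occupancy: float = Field(gt=0, description="persons per vehicle")

    @property
    def total_per_vkm(self) -> float:
        return self.ef_operational + self.ef_fuel_supply + self.ef_lifecycle


class SCCSchedule(BaseModel):
    """Social cost of carbon anchors (year, USD_2015 per tonne CO2e).

    Values are interpolated linearly between anchors and held constant
    beyond the last (and before the first) anchor.
    """

    anchors: list[tuple[int, float]]

    @field_validator("anchors")
    @classmethod
    def _check(cls, v: list[tuple[int, float]]) -> list[tuple[int, float]]:
        if not v:
            raise ValueError("SCC schedule needs at least one anchor")
        years = [y for y, _ in v]
        if any(b <= a for a, b in zip(years, years[1:])):
            raise ValueError("SCC anchor years must be strictly increasing")
        if any(val < 0 for _, val in v):
            raise ValueError("SCC values must be >= 0")
        return v


#: European-Commission recommended damage values: 44 USD_2015/t in 2015
#: rising linearly to 66 USD_2015/t by 2030, constant thereafter.
DEFAULT_SCC = SCCSchedule(anchors=[(2015, 44.0), (2030, 66.0)])


def default_scc(schedule: SCCSchedule, year: int) -> float:
    """Social cost of carbon (USD_2015/t CO2e) for ``year``.

    Linear between anchors; constant extrapolation outside the anchor range.
    """
    years = np.array([y for y, _ in schedule.anchors], dtype=float)
    vals = np.array([v for _, v in schedule.anchors], dtype=float)
    return float(np.interp(float(year), years, vals))


class CountryRecord(BaseModel):
    """Background defaults for one country."""

    country_id: str
    currency: str = "USD"
    mortality_rate: dict[str, float] = Field(
        description="deaths per person per year, keyed by age range"
    )
    pm25_background: float = Field(ge=0, description="ambient PM2.5, µg/m³")
    cycling_fatality_rate: Optional[float] = Field(
        default=None, ge=0, description="cyclist fatalities per 100 million person-km"
    )
    vsl_inputs: VSLInputs
    emission_factors: dict[str, ModeEmissionFactors] = Field(default_factory=dict)
    scc_override: Optional[SCCSchedule] = None

    @field_validator("mortality_rate")
    @classmethod
    def _rates(cls, v: dict[str, float]) -> dict[str, float]:
        missing = set(AGE_RANGES) - set(v)
        if missing:
            raise ValueError(f"mortality_rate missing age ranges: {sorted(missing)}")
        for k, r in v.items():
            if not 0 < r < 1:
                raise ValueError(f"mortality_rate[{k}]={r} outside (0,1)")
        return v


class ParameterRegistry(BaseModel):
    """Science constants plus per-country background data."""

    constants: ScienceConstants
    countries: dict[str, CountryRecord]
    scc: SCCSchedule = DEFAULT_SCC

    def country(self, country_id: str) -> CountryRecord:
        try:
            return self.countries[country_id]
        except KeyError:
            raise RegistryError(
                f"unknown country {country_id!r}; registry has {sorted(self.countries)}"
            ) from None

    def scc_for(self, country_id: str) -> SCCSchedule:
        rec = self.country(country_id)
        return rec.scc_override if rec.scc_override is not None else self.scc


# ---------------------------------------------------------------------------
# CSV schemas

_PER_MODE_KEYS = ("rr_lit", "at_lit", "cap", "ventilation_active", "traffic_factor")
_SCALAR_KEYS = (
    "ventilation_rest",
    "daily_ventilation",
    "counterfactual_traffic_factor",
    "rr_ap_per_10",
    "pa_rr_ap_adjustment",
    "p_exposed_default",
    "buildup_years_default",
    "uptake_years_default",
)
_INT_KEYS = ("buildup_years_default", "uptake_years_default")

_COUNTRY_REQUIRED = (
    ["country_id", "currency"]
    + [f"mortality_rate_{a}" for a in AGE_RANGES]
    + ["pm25_background", "gdp_pc_2005_ppp", "ppp_2005", "inflation_2005_2015", "income_growth_2005_2015"]
)
_EF_FIELDS = ("ef_operational", "ef_fuel_supply", "ef_lifecycle", "occupancy")
_COUNTRY_OPTIONAL = ["cycling_fatality_rate_per_100Mkm", "scc_override"] + [
    f"{m}_{f}" for m in MOTORIZED_MODES for f in _EF_FIELDS
]


def _parse_constants(path: Path) -> ScienceConstants:
    df = pd.read_csv(path, dtype={"key": str, "mode": str})
    for col in ("key", "mode", "value"):
        if col not in df.columns:
            raise RegistryError(f"{path}: constants file needs columns key,mode,value")
    kwargs: dict = {}
    for i, row in df.iterrows():
        key = row["key"]
        mode = row["mode"] if isinstance(row["mode"], str) and row["mode"] else None
        try:
            value = float(row["value"])
        except (TypeError, ValueError):
            raise RegistryError(f"{path} row {i}: non-numeric value for {key!r}") from None
        if key in _PER_MODE_KEYS:
            if mode not in ACTIVE_MODES:
                raise RegistryError(f"{path} row {i}: {key!r} needs mode walking|cycling")
            kwargs.setdefault(key, {})[mode] = value
        elif key in _SCALAR_KEYS:
            kwargs[key] = int(value) if key in _INT_KEYS else value
        else:
            raise RegistryError(f"{path} row {i}: unknown constant {key!r}")
    try:
        return ScienceConstants(**kwargs)
    except Exception as exc:  # pydantic ValidationError → schema error with context
        raise RegistryError(f"{path}: {exc}") from None


def _parse_scc_override(text: str) -> SCCSchedule:
    # format: "2015:40;2030:60"
    anchors = []
    for part in text.split(";"):
        year, _, val = part.partition(":")
        anchors.append((int(year), float(val)))
    return SCCSchedule(anchors=anchors)


def _parse_countries(path: Path) -> dict[str, CountryRecord]:
    df = pd.read_csv(path, dtype={"country_id": str, "currency": str, "scc_override": str})
    missing = [c for c in _COUNTRY_REQUIRED if c not in df.columns]
    if missing:
        raise RegistryError(f"{path}: missing required columns {missing}")
    countries: dict[str, CountryRecord] = {}
    for i, row in df.iterrows():
        cid = row["country_id"]
        if cid in countries:
            raise RegistryError(f"{path} row {i}: duplicate country_id {cid!r}")
        efs: dict[str, ModeEmissionFactors] = {}
        for m in MOTORIZED_MODES:
            cols = [f"{m}_{f}" for f in _EF_FIELDS]
            if all(c in df.columns and pd.notna(row[c]) for c in cols):
                efs[m] = ModeEmissionFactors(
                    **{f: float(row[f"{m}_{f}"]) for f in _EF_FIELDS}
                )
        rate_col = "cycling_fatality_rate_per_100Mkm"
        rate = None
        if rate_col in df.columns and pd.notna(row.get(rate_col)):
            rate = float(row[rate_col])
        scc = None
        if "scc_override" in df.columns and isinstance(row.get("scc_override"), str) and row["scc_override"]:
            scc = _parse_scc_override(row["scc_override"])
        try:
            countries[cid] = CountryRecord(
                country_id=cid,
                currency=row["currency"],
                mortality_rate={a: float(row[f"mortality_rate_{a}"]) for a in AGE_RANGES},
                pm25_background=float(row["pm25_background"]),
                cycling_fatality_rate=rate,
                vsl_inputs=VSLInputs(
                    gdp_pc_2005_ppp=float(row["gdp_pc_2005_ppp"]),
                    ppp_2005=float(row["ppp_2005"]),
                    inflation_2005_2015=float(row["inflation_2005_2015"]),
                    income_growth_2005_2015=float(row["income_growth_2005_2015"]),
                ),
                emission_factors=efs,
                scc_override=scc,
            )
        except Exception as exc:
            raise RegistryError(f"{path} row {i} ({cid!r}): {exc}") from None
    if not countries:
        raise RegistryError(f"{path}: no country rows")
    return countries


def _apply_overrides(registry: ParameterRegistry, overrides: dict) -> ParameterRegistry:
    data = registry.model_dump()
    for key, val in (overrides.get("constants") or {}).items():
        if isinstance(val, dict) and key in data["constants"] and isinstance(data["constants"][key], dict):
            data["constants"][key].update(val)
        else:
            data["constants"][key] = val
    for cid, patch in (overrides.get("countries") or {}).items():
        if cid not in data["countries"]:
            raise RegistryError(f"overrides reference unknown country {cid!r}")
        for key, val in patch.items():
            if isinstance(val, dict) and isinstance(data["countries"][cid].get(key), dict):
                data["countries"][cid][key].update(val)
            else:
                data["countries"][cid][key] = val
    if "scc" in overrides:
        data["scc"] = {"anchors": [tuple(a) for a in overrides["scc"]]}
    try:
        return ParameterRegistry(**data)
    except Exception as exc:
        raise RegistryError(f"overrides: {exc}") from None


def load_registry(
    constants_path: str | Path,
    countries_path: str | Path,
    overrides_path: str | Path | None = None,
) -> ParameterRegistry:
    """Load and validate the registry from its CSV (plus optional YAML) files."""
    constants_path, countries_path = Path(constants_path), Path(countries_path)
    for p in (constants_path, countries_path):
        if not p.exists():
            raise RegistryError(f"registry file not found: {p}")
    reg = ParameterRegistry(
        constants=_parse_constants(constants_path),
        countries=_parse_countries(countries_path),
    )
    if overrides_path is not None:
        with open(overrides_path) as fh:
            overrides = yaml.safe_load(fh) or {}
        reg = _apply_overrides(reg, overrides)
    return reg


def load_registry_dir(directory: str | Path) -> ParameterRegistry:
    """Load ``constants.csv`` + ``countries.csv`` (+ ``overrides.yaml``) from a directory."""
    d = Path(directory)
    overrides = d / "overrides.yaml"
    return load_registry(
        d / "constants.csv",
        d / "countries.csv",
        overrides if overrides.exists() else None,
    )


def load_default_registry() -> ParameterRegistry:
    """Registry backed by the synthetic fixture files shipped with the package."""
    from importlib.resources import files

    data = files("heatwc") / "data"
    return load_registry(str(data / "constants.csv"), str(data / "countries.csv"))


# ---------------------------------------------------------------------------
# Writing and fixture generation

def write_registry(registry: ParameterRegistry, directory: str | Path) -> tuple[Path, Path]:
    """Write the registry back to ``constants.csv`` and ``countries.csv``.

    Round-trips exactly through :func:`load_registry`.
    """
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    c = registry.constants
    rows = []
    for key in _PER_MODE_KEYS:
        for mode in ACTIVE_MODES:
            rows.append({"key": key, "mode": mode, "value": getattr(c, key)[mode]})
    for key in _SCALAR_KEYS:
        rows.append({"key": key, "mode": "", "value": getattr(c, key)})
    constants_path = d / "constants.csv"
    pd.DataFrame(rows, columns=["key", "mode", "value"]).to_csv(constants_path, index=False)

    crows = []
    for cid, rec in registry.countries.items():
        row: dict = {"country_id": cid, "currency": rec.currency}
        for a in AGE_RANGES:
            row[f"mortality_rate_{a}"] = rec.mortality_rate[a]
        row["pm25_background"] = rec.pm25_background
        row["cycling_fatality_rate_per_100Mkm"] = (
            "" if rec.cycling_fatality_rate is None else rec.cycling_fatality_rate
        )
        v = rec.vsl_inputs
        row.update(
            gdp_pc_2005_ppp=v.gdp_pc_2005_ppp,
            ppp_2005=v.ppp_2005,
            inflation_2005_2015=v.inflation_2005_2015,
            income_growth_2005_2015=v.income_growth_2005_2015,
        )
        for m in MOTORIZED_MODES:
            ef = rec.emission_factors.get(m)
            for f in _EF_FIELDS:
                row[f"{m}_{f}"] = getattr(ef, f) if ef is not None else ""
        row["scc_override"] = (
            ";".join(f"{y}:{val:g}" for y, val in rec.scc_override.anchors)
            if rec.scc_override is not None
            else ""
        )
        crows.append(row)
    cols = _COUNTRY_REQUIRED[:2] + [f"mortality_rate_{a}" for a in AGE_RANGES] + [
        "pm25_background",
        "cycling_fatality_rate_per_100Mkm",
        "gdp_pc_2005_ppp",
        "ppp_2005",
        "inflation_2005_2015",
        "income_growth_2005_2015",
    ] + [f"{m}_{f}" for m in MOTORIZED_MODES for f in _EF_FIELDS] + ["scc_override"]
    countries_path = d / "countries.csv"
    pd.DataFrame(crows, columns=cols).to_csv(countries_path, index=False)
    return constants_path, countries_path


def generate_fixture_registry(
    seed: int, n_countries: int = 3, out_dir: str | Path | None = None
) -> ParameterRegistry:
    """Synthetic country registry emulating the WHO background databases.

    Deterministic given ``seed``.  Draws plausible European-range values:
    mortality rates per age band, ambient PM2.5, cyclist fatality rates,
    GDP/PPP inputs for VSL, and car/bus/motorcycle emission factors.  The
    last country omits the cycling fatality rate so the crash pathway's
    refusal path is exercised by fixtures.  If ``out_dir`` is given the
    registry is also written there as CSV.
    """
    if n_countries < 1:
        raise ValueError("n_countries must be >= 1")
    rng = np.random.default_rng(seed)

    def r(lo: float, hi: float, nd: int = 6) -> float:
        return round(float(rng.uniform(lo, hi)), nd)

    countries: dict[str, CountryRecord] = {}
    for i in range(n_countries):
        cid = f"ZZ{chr(65 + i % 26)}" + (str(i // 26) if i >= 26 else "")
        mr_20_44 = r(0.0008, 0.0016)
        mr_45_64 = r(0.004, 0.009)
        mr_45_74 = mr_45_64 + r(0.003, 0.007)
        mr_20_64 = r(0.002, 0.004)
        mr_20_74 = mr_20_64 + r(0.001, 0.003)
        has_crash_rate = i < n_countries - 1 or n_countries == 1
        countries[cid] = CountryRecord(
            country_id=cid,
            currency=f"{cid}D",
            mortality_rate={
                "20_44": mr_20_44,
                "45_64": mr_45_64,
                "45_74": round(mr_45_74, 6),
                "20_64": mr_20_64,
                "20_74": round(mr_20_74, 6),
            },
            pm25_background=r(6.0, 25.0, 3),
            cycling_fatality_rate=r(0.5, 2.5, 4) if has_crash_rate else None,
            vsl_inputs=VSLInputs(
                gdp_pc_2005_ppp=r(15000, 45000, 1),
                ppp_2005=r(0.6, 1.8, 4),
                inflation_2005_2015=r(0.10, 0.30, 4),
                income_growth_2005_2015=r(0.05, 0.25, 4),
            ),
            emission_factors={
                "car": ModeEmissionFactors(
                    ef_operational=r(150, 220, 2),
                    ef_fuel_supply=r(25, 45, 2),
                    ef_lifecycle=r(30, 50, 2),
                    occupancy=r(1.4, 1.8, 3),
                ),
                "bus": ModeEmissionFactors(
                    ef_operational=r(700, 1100, 2),
                    ef_fuel_supply=r(90, 160, 2),
                    ef_lifecycle=r(60, 120, 2),
                    occupancy=r(10, 20, 3),
                ),
                "motorcycle": ModeEmissionFactors(
                    ef_operational=r(90, 130, 2),
                    ef_fuel_supply=r(15, 30, 2),
                    ef_lifecycle=r(15, 30, 2),
                    occupancy=r(1.0, 1.2, 3),
                ),
            },
        )
    registry = ParameterRegistry(constants=ScienceConstants(), countries=countries)
    if out_dir is not None:
        write_registry(registry, out_dir)
    return registry
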