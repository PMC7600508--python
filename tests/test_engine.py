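"""End-to-end engine: use-case validation, orchestration, determinism."""

import json

import numpy as np
import pytest
from click.testing import CliRunner

from heatwc import (
    AssessmentConfig,
    AssessmentValidationError,
    PAAssessmentInput,
    pa_impact,
    run_assessment,
    validate,
)
from heatwc.cli import main as cli_main
from conftest import DATA_DIR, REPO_ROOT


def base_config(registry, **over):
    data = {
        "country": "ZZA",
        "comparison": "single_case",
        "modes": ["cycling"],
        "pathways": ["physical_activity"],
        "timeframe": {"reference_year": 2020, "assessment_years": 10,
                      "discount_rate": 0.05},
        "population": {"size": 100000, "type": "general_population",
                       "age_range": "average"},
        "travel": {
            "cycling": {"reference": {"mode": "cycling", "unit": "minutes", "value": 20}}
        },
    }
    data.update(over)
    return AssessmentConfig.from_dict(data)


def two_case(registry, ref_min=10, comp_min=20, **over):
    cfg = {
        "comparison": "two_case",
        "travel": {
            "cycling": {
                "reference": {"mode": "cycling", "unit": "minutes", "value": ref_min},
                "comparison": {"mode": "cycling", "unit": "minutes", "value": comp_min},
            }
        },
        "timeframe": {"reference_year": 2020, "assessment_years": 10,
                      "uptake_years": 2, "buildup_years": 5, "discount_rate": 0.05},
    }
    cfg.update(over)
    return base_config(registry, **cfg)


class TestValidation:
    def test_counts_at_country_scale_rejected(self, registry):
        cfg = base_config(
            registry,
            travel={"cycling": {"reference": {
                "mode": "cycling", "unit": "counts", "value": 100,
                "minutes_per_count": 10,
            }}},
        )
        errors = validate(cfg, registry)
        assert any("sub-city" in e for e in errors)

    def test_crash_for_walking_only_rejected(self, registry):
        cfg = base_config(
            registry,
            modes=["walking"],
            pathways=["crash"],
            travel={"walking": {"reference": {
                "mode": "walking", "unit": "minutes", "value": 20}}},
        )
        errors = validate(cfg, registry)
        assert any("cycling only" in e for e in errors)

    def test_crash_without_country_rate_rejected(self, registry):
        # ZZC is the fixture country without a cycling fatality rate
        cfg = base_config(registry, country="ZZC", pathways=["physical_activity", "crash"])
        errors = validate(cfg, registry)
        assert any("fatality rate" in e for e in errors)

    def test_crash_at_sub_city_scale_rejected(self, registry):
        cfg = base_config(registry, scale="sub_city", pathways=["crash"])
        assert any("sub-city" in e for e in validate(cfg, registry))

    def test_errors_are_aggregated_not_first_failure(self, registry):
        cfg = base_config(
            registry,
            country="NOPE",
            modes=["walking"],
            pathways=["crash"],
            travel={"walking": {"reference": {
                "mode": "walking", "unit": "counts", "value": 10,
                "minutes_per_count": 5}}},
        )
        errors = validate(cfg, registry)
        assert len(errors) >= 3

    def test_well_formed_two_case_passes(self, registry):
        cfg = two_case(registry, pathways=["physical_activity", "air_pollution",
                                           "crash", "carbon"])
        assert validate(cfg, registry) == []

    def test_run_raises_aggregated_error(self, registry):
        cfg = base_config(registry, country="NOPE")
        with pytest.raises(AssessmentValidationError):
            run_assessment(cfg, registry)


class TestRunAssessment:
    def test_zero_contrast_zero_impacts_and_values(self, registry):
        cfg = two_case(registry, ref_min=20, comp_min=20,
                       pathways=["physical_activity", "air_pollution", "carbon"])
        res = run_assessment(cfg, registry)
        for p in res.impacts:
            assert np.allclose(p.series.values, 0.0)
        assert res.monetized.combined_total == pytest.approx(0.0)

    def test_doubling_single_case_volume_doubles_pa_deaths_prevented(self, registry):
        lo = run_assessment(base_config(registry), registry)
        hi = run_assessment(
            base_config(registry, travel={"cycling": {"reference": {
                "mode": "cycling", "unit": "minutes", "value": 40}}}),
            registry,
        )
        # 40 min/day cycling = 280 min/wk, still below the 450 min/wk cap;
        # exact doubling holds up to the O(p_e) PAF denominator term
        assert hi.impacts[0].series.total() == pytest.approx(
            2 * lo.impacts[0].series.total(), rel=1e-3
        )

    def test_single_case_forces_steady_state(self, registry):
        cfg = base_config(registry, timeframe={
            "reference_year": 2020, "assessment_years": 10,
            "uptake_years": 5, "buildup_years": 5, "discount_rate": 0.0})
        res = run_assessment(cfg, registry)
        assert res.timeframe.uptake_years == 0
        assert res.timeframe.buildup_years == 0
        # constant annual impact
        assert np.ptp(res.impacts[0].series.values) == pytest.approx(0.0)

    def test_removing_ap_pathway_leaves_pa_unchanged(self, registry):
        both = run_assessment(
            two_case(registry, pathways=["physical_activity", "air_pollution"]),
            registry,
        )
        pa_only = run_assessment(two_case(registry, pathways=["physical_activity"]),
                                 registry)
        pa_both = next(p for p in both.impacts if p.pathway == "physical_activity")
        pa_alone = pa_only.impacts[0]
        # default pa_rr_ap_adjustment is neutral
        np.testing.assert_allclose(pa_both.series.values, pa_alone.series.values)

    def test_engine_equals_hand_composed_module_calls(self, registry):
        """Integration equals unit composition for the PA pathway."""
        cfg = two_case(registry, ref_min=10, comp_min=20)
        res = run_assessment(cfg, registry)
        c = registry.constants
        country = registry.country("ZZA")
        common = dict(
            mode="cycling", rr_lit=c.rr_lit["cycling"], at_lit=c.at_lit["cycling"],
            cap=c.cap["cycling"], mr_pop=country.mortality_rate["20_64"],
            p_e=c.p_exposed_default, pop=100000,
        )
        steady = pa_impact(
            PAAssessmentInput.from_minutes_per_day(10, **common),
            PAAssessmentInput.from_minutes_per_day(20, **common),
        )
        k = np.arange(1, 11)
        expected = steady * np.minimum(k / 7, 1.0)  # uptake 2 + buildup 5
        np.testing.assert_allclose(res.impacts[0].series.values, expected, rtol=1e-12)

    def test_deterministic_repeat_runs_bit_identical(self, registry, demo_config):
        a = run_assessment(demo_config, registry).to_json()
        b = run_assessment(demo_config, registry).to_json()
        assert a == b

    def test_golden_demo_report(self, registry, demo_config):
        """The committed demo assessment reproduces its report byte-for-byte."""
        report = run_assessment(demo_config, registry).to_json() + "\n"
        golden = (DATA_DIR / "golden_report.json").read_text()
        assert report == golden

    def test_audit_trail_has_intermediates(self, registry):
        res = run_assessment(
            two_case(registry, pathways=["physical_activity", "air_pollution"]),
            registry,
        )
        mode_audit = res.audit["modes"]["cycling"]
        assert "reference_volume" in mode_audit
        assert "rr_comparison" in mode_audit["physical_activity"]
        assert "delta_c_comparison" in mode_audit["air_pollution"]


class TestCLI:
    def test_validate_and_run_demo(self, tmp_path):
        runner = CliRunner()
        config = str(REPO_ROOT / "examples" / "demo_config.yaml")
        ok = runner.invoke(cli_main, ["validate", config])
        assert ok.exit_code == 0, ok.output
        out = runner.invoke(cli_main, ["run", config, "--out", str(tmp_path),
                                       "--format", "csv"])
        assert out.exit_code == 0, out.output
        report = json.loads((tmp_path / "report.json").read_text())
        assert report["totals"]["combined"] > 0
        assert (tmp_path / "impacts_by_year.csv").exists()

    def test_invalid_config_exits_with_validation_code(self, tmp_path):
        bad = tmp_path / "bad.yaml"
        bad.write_text(
            "country: NOPE\nmodes: [walking]\npathways: [crash]\n"
            "population: {size: 100}\n"
            "travel: {walking: {reference: {mode: walking, unit: minutes, value: 10}}}\n"
        )
        res = CliRunner().invoke(cli_main, ["validate", str(bad)])
        assert res.exit_code == 1

    def test_fixtures_command_round_trips(self, tmp_path):
        res = CliRunner().invoke(
            cli_main, ["fixtures", "--seed", "3", "--out", str(tmp_path / "reg")]
        )
        assert res.exit_code == 0, res.output
        ok = CliRunner().invoke(
            cli_main,
            ["validate", str(REPO_ROOT / "examples" / "demo_config.yaml"),
             "--registry", str(tmp_path / "reg")],
        )
        assert ok.exit_code == 0, ok.output
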