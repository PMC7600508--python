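"""Temporal schedules: uptake, build-up, crash-rate interpolation, discounting.

The brute-force year-loop oracle below is written independently of the
vectorized implementations and is the reference for the random-configuration
equivalence suite.
"""

import numpy as np
import pytest

from heatwc import (
    TimeFrame,
    YearSeries,
    buildup_series,
    crash_risk_series,
    discount_series,
    effect_fraction,
    uptake_series,
)

# ---------------------------------------------------------------------------
# independent year-loop oracle (plain Python, one year at a time)


def oracle_uptake(ref, comp, n, u):
    out = []
    for k in range(1, n + 1):
        frac = 1.0 if u == 0 else min(k / u, 1.0)
        out.append(ref + (comp - ref) * frac)
    return out


def oracle_effect(full_value, n, u, b):
    span = u + b
    out = []
    for k in range(1, n + 1):
        frac = 1.0 if span == 0 else min(k / span, 1.0)
        out.append(full_value * frac)
    return out


def oracle_crash_rates(r_ref, r_comp, n):
    if n == 1:
        return [r_comp]
    return [r_ref + (r_comp - r_ref) * (k - 1) / (n - 1) for k in range(1, n + 1)]


def oracle_discount(values, start_year, rate, discount_year):
    return [
        v / (1.0 + rate) ** ((start_year + i) - discount_year)
        for i, v in enumerate(values)
    ]


def tf(n=20, u=0, b=0, rate=0.0, ref_year=2020, discount_year=None):
    return TimeFrame(
        reference_year=ref_year,
        assessment_years=n,
        uptake_years=u,
        buildup_years=b,
        discount_rate=rate,
        discount_year=discount_year,
    )


class TestUptake:
    def test_comparison_level_reached_at_uptake_end(self):
        s = uptake_series(100, 200, tf(n=20, u=5))
        assert s.values[4] == pytest.approx(200.0)  # year 5
        assert np.all(s.values[4:] == 200.0)

    def test_linear_rule_first_year(self):
        s = uptake_series(100, 200, tf(n=20, u=5))
        assert s.values[0] == pytest.approx(120.0)

    def test_zero_uptake_is_step_change(self):
        s = uptake_series(100, 200, tf(n=5, u=0))
        assert np.all(s.values == 200.0)

    def test_monotone_and_bounded_between_cases(self):
        for ref, comp in [(100, 200), (200, 100)]:
            s = uptake_series(ref, comp, tf(n=15, u=7))
            lo, hi = min(ref, comp), max(ref, comp)
            assert np.all((s.values >= lo) & (s.values <= hi))
            diffs = np.diff(s.values)
            assert np.all(diffs >= 0) if comp >= ref else np.all(diffs <= 0)


class TestBuildup:
    def test_no_buildup_is_identity(self):
        contrast = YearSeries(2021, np.arange(10.0))
        out = buildup_series(contrast, 0, 0)
        assert np.array_equal(out.values, contrast.values)

    def test_step_contrast_ramps_linearly(self):
        # full contrast from year 1, 5-year build-up: effect(k) = 100 k/5
        contrast = YearSeries(2021, np.full(20, 100.0))
        out = buildup_series(contrast, 5, 0)
        assert out.values[2] == pytest.approx(60.0)  # year 3
        assert out.values[4] == pytest.approx(100.0)
        assert int(np.argmax(out.values >= out.values.max())) + 1 == 5

    def test_full_effect_first_reached_at_uptake_plus_buildup(self):
        frame = tf(n=20, u=5, b=5)
        contrast = uptake_series(0, 100, frame)
        out = buildup_series(contrast, 5, 5)
        first_full = int(np.argmax(np.isclose(out.values, 100.0))) + 1
        assert first_full == 10
        assert out.values[8] < 100.0  # year 9 still below maximum

    def test_output_bounded_by_contrast_maximum(self):
        contrast = uptake_series(0, 50, tf(n=12, u=4))
        out = buildup_series(contrast, 3, 4)
        assert np.all(out.values <= contrast.values.max() + 1e-12)

    def test_converges_to_contrast_once_constant(self):
        contrast = uptake_series(10, 40, tf(n=30, u=6))
        out = buildup_series(contrast, 5, 6)
        assert np.allclose(out.values[11:], contrast.values[11:])


class TestCrashRateInterpolation:
    def test_equal_rates_give_constant_series(self):
        s = crash_risk_series(1.5, 1.5, tf(n=10))
        assert np.all(s.values == 1.5)

    def test_midpoint_of_linear_interpolation(self):
        s = crash_risk_series(2.0, 1.0, tf(n=11))
        assert s.values[5] == pytest.approx(1.5)  # year 6

    def test_single_year_period_uses_comparison_rate(self):
        s = crash_risk_series(2.0, 1.0, tf(n=1))
        assert s.values.tolist() == [1.0]

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            crash_risk_series(-1.0, 1.0, tf())


class TestDiscounting:
    def test_zero_rate_is_identity(self):
        s = YearSeries(2021, np.array([100.0, 200.0]))
        out = discount_series(s, tf(n=2, rate=0.0))
        assert np.array_equal(out.values, s.values)

    def test_one_year_ahead_at_five_percent(self):
        s = YearSeries(2021, np.array([100.0]))
        out = discount_series(s, tf(n=1, rate=0.05, discount_year=2020))
        assert out.values[0] == pytest.approx(100 / 1.05)  # 95.238095

    def test_value_in_discount_year_unchanged(self):
        s = YearSeries(2021, np.array([100.0]))
        out = discount_series(s, tf(n=1, rate=0.05, discount_year=2021))
        assert out.values[0] == pytest.approx(100.0)

    def test_years_before_discount_year_are_inflated(self):
        s = YearSeries(2021, np.array([100.0]))
        out = discount_series(s, tf(n=1, rate=0.05, discount_year=2025))
        assert out.values[0] == pytest.approx(100 * 1.05**4)

    def test_total_non_increasing_in_rate(self):
        s = YearSeries(2021, np.linspace(10, 100, 15))
        totals = [
            discount_series(s, tf(n=15, rate=r)).total() for r in (0.0, 0.02, 0.05, 0.1)
        ]
        assert all(b <= a for a, b in zip(totals, totals[1:]))


class TestOracleEquivalence:
    def test_engine_matches_year_loop_on_random_configurations(self):
        """1,000 random time frames: vectorized schedules vs the year loop."""
        rng = np.random.default_rng(12345)
        for _ in range(1000):
            n = int(rng.integers(1, 41))
            u = int(rng.integers(0, 11))
            b = int(rng.integers(0, 11))
            ref, comp = rng.uniform(0, 500, size=2)
            rate = float(rng.uniform(0, 0.12))
            ref_year = int(rng.integers(1990, 2040))
            dy = ref_year + int(rng.integers(-3, 8))
            frame = tf(n=n, u=u, b=b, rate=rate, ref_year=ref_year, discount_year=dy)

            got = uptake_series(ref, comp, frame)
            np.testing.assert_allclose(
                got.values, oracle_uptake(ref, comp, n, u), rtol=0, atol=1e-9
            )

            contrast = comp - ref
            eff = effect_fraction(frame) * contrast
            np.testing.assert_allclose(
                eff.values, oracle_effect(contrast, n, u, b), rtol=0, atol=1e-9
            )

            r1, r2 = rng.uniform(0, 5, size=2)
            np.testing.assert_allclose(
                crash_risk_series(r1, r2, frame).values,
                oracle_crash_rates(r1, r2, n),
                rtol=1e-12, atol=1e-9,
            )

            money = YearSeries(ref_year + 1, rng.uniform(0, 1e6, size=n))
            np.testing.assert_allclose(
                discount_series(money, frame).values,
                oracle_discount(money.values, ref_year + 1, rate, dy),
                rtol=1e-9, atol=1e-9,
            )
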