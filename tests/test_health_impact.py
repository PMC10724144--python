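"""WHO exceedance statistics, Eq.-of-record mortality burden, lockdown windows."""

import numpy as np
import pytest

from gaplesspm.health_impact import (
    RiskModel,
    ThresholdSet,
    adjust_population,
    detect_lockdown_window,
    exceedance_days_grid,
    exceedance_stats,
    mortality_burden,
    period_difference,
    populated_area_fractions,
    population_weighted_mean,
    relative_risk,
)


class TestThresholds:
    def test_default_ladder(self):
        t = ThresholdSet()
        assert list(t.as_ladder().values()) == [15.0, 25.0, 37.5, 50.0, 75.0]

    def test_non_increasing_ladder_rejected(self):
        with pytest.raises(ValueError):
            ThresholdSet(aqg=30.0, it4=25.0)


class TestExceedance:
    def test_clean_series_zero_days(self):
        out = exceedance_stats(np.full(365, 10.0))
        assert out["aqg"]["days"] == 0 and out["aqg"]["percent"] == 0.0

    def test_73_of_365_days_is_20_percent(self):
        series = np.full(365, 10.0)
        series[:73] = 40.0
        out = exceedance_stats(series)
        assert out["aqg"]["percent"] == pytest.approx(20.0)

    def test_exactly_at_threshold_not_counted(self):
        out = exceedance_stats(np.array([15.0, 15.0, 16.0]))
        assert out["aqg"]["days"] == 1

    def test_missing_days_excluded_from_both_sides(self):
        series = np.array([np.nan] * 100 + [20.0] * 50 + [10.0] * 50)
        out = exceedance_stats(series)
        assert out["aqg"]["days"] == 50
        assert out["aqg"]["percent"] == pytest.approx(50.0)

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            exceedance_stats(np.full(10, np.nan))

    def test_ladder_monotone_and_matches_brute_force(self):
        rng = np.random.default_rng(0)
        t = ThresholdSet()
        for _ in range(50):
            series = rng.gamma(2.0, 15.0, 120)
            out = exceedance_stats(series, t)
            pcts = [out[k]["percent"] for k in ("aqg", "it4", "it3", "it2", "it1")]
            assert all(a >= b for a, b in zip(pcts, pcts[1:]))
            for name, level in t.as_ladder().items():
                brute = sum(1 for v in series if v > level)
                assert out[name]["days"] == brute


class TestPopulationWeighting:
    def test_uniform_population_is_arithmetic_mean(self):
        vals = np.array([[1.0, 2.0], [3.0, 4.0]])
        pop = np.ones_like(vals)
        assert population_weighted_mean(vals, pop) == pytest.approx(2.5)

    def test_point_mass_population(self):
        vals = np.array([[1.0, 2.0], [3.0, 4.0]])
        pop = np.zeros_like(vals)
        pop[1, 0] = 10.0
        assert population_weighted_mean(vals, pop) == 3.0

    def test_hand_example(self):
        assert population_weighted_mean(
            np.array([10.0, 30.0]), np.array([1.0, 3.0])
        ) == pytest.approx(25.0)

    def test_zero_population_rejected(self):
        with pytest.raises(ValueError, match="population"):
            population_weighted_mean(np.array([1.0]), np.array([0.0]))


class TestPopulatedAreaFractions:
    def test_four_cell_toy(self):
        days = np.array([0, 1, 7, 30])
        density = np.full(4, 5.0)
        out = populated_area_fractions({"aqg": days}, density)
        assert out["aqg"][1] == 75.0
        assert out["aqg"][7] == 50.0
        assert out["aqg"][30] == 25.0

    def test_saturated_exposure(self):
        days = np.full(6, 40)
        out = populated_area_fractions(days, np.full(6, 2.0))
        assert all(v == 100.0 for v in out["threshold"].values())

    def test_monotone_in_duration_and_threshold(self):
        rng = np.random.default_rng(1)
        cube = rng.gamma(2.0, 15.0, (60, 5, 5))
        density = rng.uniform(0, 10, (5, 5))
        t = ThresholdSet()
        exceed = {k: exceedance_days_grid(cube, v)
                  for k, v in t.as_ladder().items()}
        out = populated_area_fractions(exceed, density)
        for k in out:
            assert out[k][1] >= out[k][7] >= out[k][30]
        for d in (1, 7, 30):
            ladder = [out[k][d] for k in ("aqg", "it4", "it3", "it2", "it1")]
            assert all(a >= b for a, b in zip(ladder, ladder[1:]))

    def test_unpopulated_cells_excluded(self):
        days = np.array([30, 30])
        density = np.array([0.5, 5.0])  # only second cell is populated
        out = populated_area_fractions(days, density)
        assert out["threshold"][1] == 100.0

    def test_no_populated_cells_rejected(self):
        with pytest.raises(ValueError, match="density"):
            populated_area_fractions(np.array([1]), np.array([0.1]))


class TestAdjustPopulation:
    def test_matching_sums_identity(self):
        pop = np.array([100.0, 200.0])
        out = adjust_population(pop, np.array(["A", "A"]), {"A": 300.0})
        np.testing.assert_allclose(out, pop)

    def test_ratio_scaling(self):
        pop = np.array([400.0, 500.0])
        out = adjust_population(pop, np.array(["A", "A"]), {"A": 1000.0})
        np.testing.assert_allclose(out, pop * 10.0 / 9.0)
        assert out.sum() == pytest.approx(1000.0, rel=1e-9)

    def test_countries_scaled_independently(self):
        pop = np.array([100.0, 50.0])
        out = adjust_population(pop, np.array(["A", "B"]),
                                {"A": 200.0, "B": 50.0})
        np.testing.assert_allclose(out, [200.0, 50.0])

    def test_zero_grid_sum_with_total_rejected(self):
        with pytest.raises(ValueError, match="zero grid"):
            adjust_population(np.array([0.0]), np.array(["A"]), {"A": 5.0})


class TestRelativeRisk:
    def test_at_counterfactual_rr_is_one(self):
        assert relative_risk(0.0) == 1.0

    def test_per_10_increment_matches_reported_rr(self):
        assert relative_risk(10.0) == pytest.approx(1.0065, abs=1e-12)

    def test_per_20_is_square(self):
        assert relative_risk(20.0) == pytest.approx(1.0065**2, abs=1e-12)

    def test_monotone_and_below_counterfactual_clamped(self):
        m = RiskModel(c0=5.0)
        cs = np.linspace(0, 100, 50)
        rr = relative_risk(cs, m)
        assert np.all(np.diff(rr) >= 0)
        assert relative_risk(2.0, m) == 1.0

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            relative_risk(-1.0)


class TestMortalityBurden:
    def test_zero_at_counterfactual(self):
        out = mortality_burden(0.0, 1e6, 0.008, 365)
        assert out["mb"] == 0.0

    def test_hand_computed_example(self):
        out = mortality_burden(10.0, 1e6, 0.008, 365)
        exact = (0.0065 / 1.0065) * 1e6 * 0.008 / 365
        assert out["mb"] == pytest.approx(exact, rel=1e-12)
        assert out["mb"] == pytest.approx(0.14153, abs=5e-5)

    def test_linearity_in_pop_and_bmr(self):
        base = mortality_burden(37.0, 1e5, 0.01, 365)["mb"]
        assert mortality_burden(37.0, 2e5, 0.01, 365)["mb"] == pytest.approx(
            2 * base, rel=1e-12
        )
        assert mortality_burden(37.0, 1e5, 0.02, 365)["mb"] == pytest.approx(
            2 * base, rel=1e-12
        )

    def test_ci_ordering(self):
        out = mortality_burden(50.0, 1e6, 0.008, 365)
        assert out["mb_lo"] <= out["mb"] <= out["mb_hi"]

    def test_small_beta_linear_limit(self):
        model = RiskModel()
        for dc in (1.0, 5.0, 10.0):
            mb = mortality_burden(dc, 1e6, 0.008, 365, model)["mb"]
            approx = model.beta * dc * 1e6 * 0.008 / 365
            assert abs(mb - approx) / approx < 0.01

    def test_country_aggregation_consistency(self):
        rng = np.random.default_rng(3)
        c = rng.gamma(3.0, 15.0, (10, 4, 4))
        pop = rng.uniform(0, 1e4, (4, 4))
        out = mortality_burden(c, pop[None], 0.008, 365)
        total = out["mb"].sum()
        by_cell = sum(out["mb"][:, i, j].sum()
                      for i in range(4) for j in range(4))
        assert by_cell == pytest.approx(total, rel=1e-9)

    def test_bad_year_length_rejected(self):
        with pytest.raises(ValueError, match="365 or 366"):
            mortality_burden(10.0, 1e6, 0.008, 360)


def brute_force_window(si, plateau_frac=0.5, min_max_si=20.0):
    """Enumerate all contiguous intervals; pick the maximal one containing
    the earliest argmax with SI >= plateau_frac*max throughout."""
    m = si.max()
    if m <= min_max_si:
        return None
    peak = int(np.argmax(si))
    level = plateau_frac * m
    best = None
    for a in range(len(si)):
        for b in range(a + 1, len(si) + 1):
            if a <= peak < b and np.all(si[a:b] >= level):
                if best is None or (b - a) > (best[1] - best[0]):
                    best = (a, b)
    return best


class TestLockdownWindow:
    def test_zero_series_none(self):
        assert detect_lockdown_window(np.zeros(100)) is None

    def test_max_15_does_not_surpass_gate(self):
        si = np.zeros(100)
        si[40:60] = 15.0
        assert detect_lockdown_window(si) is None

    def test_ramp_plateau_example_matches_brute_force(self):
        si = np.zeros(100)
        si[50:60] = np.linspace(0, 80, 10, endpoint=False)
        si[60:90] = 80.0
        si[90:100] = np.linspace(80, 0, 10, endpoint=False)
        got = detect_lockdown_window(si)
        assert got == brute_force_window(si)
        a, b = got
        assert np.all(si[a:b] >= 40.0)

    def test_randomized_series_match_brute_force(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            si = np.clip(
                np.cumsum(rng.normal(0, 8, 60)) + rng.uniform(0, 30), 0, 100
            )
            assert detect_lockdown_window(si) == brute_force_window(si)

    def test_incomplete_series_rejected(self):
        with pytest.raises(ValueError, match="complete"):
            detect_lockdown_window(np.array([1.0, np.nan]))


class TestPeriodDifference:
    def test_identical_cubes_zero_change(self):
        rng = np.random.default_rng(0)
        cube = rng.gamma(3.0, 15.0, (30, 3, 3))
        pop = rng.uniform(10, 100, (3, 3))
        out = period_difference(cube, cube, (5, 20), pop, 0.008, 365)
        assert out["pwm_percent_change"] == 0.0
        assert out["delta_deaths"] == 0.0

    def test_baseline_double_gives_minus_50_percent(self):
        rng = np.random.default_rng(1)
        cube = rng.gamma(3.0, 15.0, (30, 3, 3))
        pop = rng.uniform(10, 100, (3, 3))
        out = period_difference(cube, 2 * cube, (0, 30), pop, 0.008, 365)
        assert out["pwm_percent_change"] == pytest.approx(-50.0)

    def test_two_cell_two_day_toy_hand_computed(self):
        # year A: cells at 20 and 40 both days; baseline: 30 and 50
        a = np.array([[[20.0, 40.0]], [[20.0, 40.0]]])
        b = np.array([[[30.0, 50.0]], [[30.0, 50.0]]])
        pop = np.array([[1000.0, 3000.0]])
        bmr, n = 0.01, 365
        model = RiskModel()

        def mb_sum(cube):
            total = 0.0
            for d in range(2):
                for j in range(2):
                    rr = np.exp(model.beta * cube[d, 0, j])
                    total += (rr - 1) / rr * pop[0, j] * bmr / n
            return total

        out = period_difference(a, b, (0, 2), pop, bmr, n, model)
        pwm_a = (20 * 1000 + 40 * 3000) / 4000
        pwm_b = (30 * 1000 + 50 * 3000) / 4000
        assert out["pwm_percent_change"] == pytest.approx(
            100 * (pwm_a - pwm_b) / pwm_b
        )
        assert out["delta_deaths"] == pytest.approx(
            mb_sum(a) - mb_sum(b), rel=1e-9
        )

    def test_window_outside_calendar_rejected(self):
        cube = np.ones((10, 2, 2))
        with pytest.raises(ValueError, match="window"):
            period_difference(cube, cube, (5, 20), np.ones((2, 2)), 0.01, 365)
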