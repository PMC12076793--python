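"""One-way sensitivity analysis and break-even threshold searches."""

import pytest

from microcea import BracketError, breakeven, compare, one_way, tornado
from microcea.dsa import apply_value
from microcea.params import ConfigValidationError, maintenance_cost_per_sample


class TestOneWay:
    def test_baseline_only_matches_deterministic_run(self, baseline):
        frame = one_way(baseline, "test.prevalence", [0.40], "ceftriaxone_gentamicin")
        det = compare(baseline, "ceftriaxone_gentamicin")
        assert len(frame) == 1
        assert frame.loc[0, "delta_cost"] == pytest.approx(det.delta_cost)
        assert frame.loc[0, "is_baseline"]

    def test_deaths_averted_increase_with_prevalence(self, baseline):
        frame = one_way(baseline, "test.prevalence", [0.2, 0.4, 0.6],
                        "ceftriaxone_gentamicin")
        deaths = list(frame.sort_values("value")["deaths_averted"])
        assert deaths == sorted(deaths)
        assert deaths[0] < deaths[-1]

    def test_baseline_value_always_included(self, baseline):
        frame = one_way(baseline, "costs.icu_cost_per_day", [200.0, 400.0],
                        "meropenem_vancomycin")
        assert 300.0 in set(frame["value"])

    def test_out_of_bounds_value_aborts_scenario(self, baseline):
        with pytest.raises(ConfigValidationError, match="prevalence"):
            one_way(baseline, "test.prevalence", [0.2, 1.4], "ceftriaxone_gentamicin")

    def test_doubling_bottles_shifts_cost_by_lab_increment_only(self, baseline):
        frame = one_way(baseline, "test.bottles_per_patient", [2, 4],
                        "ampicillin_gentamicin")
        frame = frame.set_index("value")
        t = baseline.test
        c = baseline.costs
        p_pos = t.prevalence * t.sensitivity + (1 - t.prevalence) * t.false_positive
        expected_bottle = (p_pos * c.culture_positive_bottle
                           + (1 - p_pos) * c.culture_negative_bottle)
        per_patient = 2 * (c.maintenance_per_sample + expected_bottle)
        delta = frame.loc[4, "delta_cost"] - frame.loc[2, "delta_cost"]
        assert delta == pytest.approx(per_patient * baseline.daly.cohort_size)
        assert frame.loc[4, "dalys_averted"] == pytest.approx(frame.loc[2, "dalys_averted"])
        assert frame.loc[4, "deaths_averted"] == pytest.approx(frame.loc[2, "deaths_averted"])

    def test_delta_cost_linear_in_maintenance_with_known_slope(self, baseline):
        values = [10.0, 40.0, 70.0, 100.0]
        frame = one_way(baseline, "costs.maintenance_per_sample", values,
                        "ceftriaxone_gentamicin").set_index("value")
        slope = baseline.test.bottles_per_patient * baseline.daly.cohort_size
        d0 = frame.loc[10.0, "delta_cost"]
        for v in values[1:]:
            assert frame.loc[v, "delta_cost"] - d0 == pytest.approx(slope * (v - 10.0))

    def test_tornado_orders_by_swing(self, baseline):
        frame = tornado(
            baseline,
            {"test.prevalence": (0.2, 0.6), "costs.ward_cost_per_day": (40.0, 60.0)},
            "ceftriaxone_gentamicin",
        )
        swings = frame.groupby("parameter", sort=False)["swing"].first()
        assert list(swings) == sorted(swings, reverse=True)


class TestBreakeven:
    def test_maintenance_threshold_agrees_with_grid_scan(self, baseline):
        res = breakeven(baseline, "maintenance_per_sample", "cost_saving",
                        (10.0, 400.0), "meropenem_vancomycin")
        assert res.below_satisfied and not res.above_satisfied
        # exhaustive cent-resolution scan around the reported threshold
        import numpy as np
        grid = np.round(np.arange(res.threshold - 0.05, res.threshold + 0.05, 0.01), 2)
        flags = []
        for m in grid:
            comp = compare(apply_value(baseline, "costs.maintenance_per_sample", float(m)),
                           "meropenem_vancomycin")
            flags.append(comp.delta_cost < 0)
        flips = [i for i in range(1, len(flags)) if flags[i] != flags[i - 1]]
        assert len(flips) == 1
        assert abs(grid[flips[0]] - res.threshold) <= 0.02

    def test_minimum_samples_is_integer_with_sign_flip(self, baseline):
        res = breakeven(baseline, "annual_samples", "cost_saving",
                        (100, 3813), "ceftriaxone_gentamicin")
        n = int(res.threshold)
        assert res.threshold == n and res.tolerance == 1.0

        def saves(k):
            return compare(apply_value(baseline, "costs.annual_samples", k),
                           "ceftriaxone_gentamicin").delta_cost < 0

        assert saves(n) and not saves(n - 1)

    def test_cost_effective_threshold_not_larger_than_cost_saving(self, baseline):
        saving = breakeven(baseline, "annual_samples", "cost_saving",
                           (100, 3813), "meropenem_vancomycin")
        effective = breakeven(baseline, "annual_samples", "cost_effective_at_wtp",
                              (100, 3813), "meropenem_vancomycin", wtp=500.0)
        assert effective.threshold <= saving.threshold

    def test_unbracketed_bounds_raise(self, baseline):
        with pytest.raises(BracketError, match="both bounds"):
            breakeven(baseline, "maintenance_per_sample", "cost_saving",
                      (1.0, 5.0), "ceftriaxone_gentamicin")

    def test_criterion_constant_without_lab_usage(self, baseline):
        # degenerate: a test that never returns positives and free bottles
        baseline.test.sensitivity = 0.0
        baseline.test.false_positive = 0.0
        baseline.costs.culture_negative_bottle = 0.0
        with pytest.raises(BracketError):
            breakeven(baseline, "maintenance_per_sample", "cost_saving",
                      (0.01, 0.02), "ceftriaxone_gentamicin")


def test_apply_value_keeps_lab_cost_pair_consistent(baseline):
    p = apply_value(baseline, "costs.maintenance_per_sample", 76.0)
    assert p.costs.annual_fixed_lab_cost == pytest.approx(76.0 * 3813)
    p = apply_value(baseline, "costs.annual_samples", 1200)
    assert p.costs.maintenance_per_sample == maintenance_cost_per_sample(131697, 1200)
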