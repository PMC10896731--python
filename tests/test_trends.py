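import numpy as np
import pandas as pd
import pytest

from yieldgap.bootstrap import bootstrap_fit
from yieldgap.quantile import ModelSpec
from yieldgap.simulate import ScenarioConfig, generate_panel
from yieldgap.trends import (
    GapSeries,
    area_fraction_significant,
    fixed_area_counterfactual,
    gap_series_from_records,
    global_average_change,
    linear_gap_trend,
    time_to_closure,
    windowed_value,
)


def make_gs(actual, attainable, area=None, years=None, units=None):
    """GapSeries from plain arrays; attainable may be (U,T) or (B,U,T)."""
    actual = np.asarray(actual, float)
    attainable = np.asarray(attainable, float)
    if attainable.ndim == 2:
        attainable = attainable[None, :, :]
    U, T = actual.shape
    area = np.ones((U, T)) if area is None else np.asarray(area, float)
    years = np.arange(1998, 1998 + T) if years is None else np.asarray(years)
    units = np.array([f"U{i}" for i in range(U)]) if units is None else np.asarray(units)
    return GapSeries(unit_ids=units, years=years, actual=actual,
                     attainable=attainable, area=area)


class TestWindowedValue:
    def test_constant_series(self):
        years = np.arange(2000, 2010)
        assert windowed_value(years, np.full(10, 3.3), np.ones(10), 2005) == pytest.approx(3.3)

    def test_equal_weight_mean(self):
        years = np.arange(2000, 2005)
        assert windowed_value(years, [1, 2, 3, 4, 5], np.ones(5), 2002) == pytest.approx(3.0)

    def test_area_weighting(self):
        years = np.array([2000, 2001])
        assert windowed_value(years, [2.0, 4.0], [1.0, 3.0], 2000) == pytest.approx(3.5)

    def test_edge_year_partial_window(self):
        years = np.arange(2000, 2005)
        # window around 2000 only covers 2000-2002
        assert windowed_value(years, [1, 2, 3, 4, 5], np.ones(5), 2000) == pytest.approx(2.0)

    def test_empty_window_is_nan(self):
        assert np.isnan(windowed_value(np.array([2000]), [1.0], [1.0], 2010))

    def test_invariant_to_unit_splitting(self):
        # one unit vs the same totals split across two sub-units
        years = np.arange(2000, 2005)
        v = np.array([2.0, 3.0, 4.0, 5.0, 6.0])
        a = np.array([4.0, 4.0, 2.0, 2.0, 2.0])
        whole = windowed_value(years, v, a, 2002)
        yy = np.concatenate([years, years])
        vv = np.concatenate([v, v])
        aa = np.concatenate([a * 0.25, a * 0.75])
        assert windowed_value(yy, vv, aa, 2002) == pytest.approx(whole)


class TestLinearTrend:
    def test_exact_linear_recovery(self):
        t = np.arange(15)
        gap = 5.0 - 0.2 * t
        gs = make_gs(np.zeros((1, 15)), np.tile(gap, (2, 1, 1)))
        tr = linear_gap_trend(gs, "U0")
        assert tr.x0 == pytest.approx(5.0, abs=1e-9)
        assert tr.x1 == pytest.approx(-0.2, abs=1e-12)
        assert tr.significance == "negative"

    def test_identical_realizations_zero_width_ci(self):
        t = np.arange(15)
        gs = make_gs(np.zeros((1, 15)), np.tile(1.0 + 0.1 * t, (3, 1, 1)))
        tr = linear_gap_trend(gs, "U0")
        assert np.ptp(tr.x1s) == 0.0 and tr.significance == "positive"

    def test_white_noise_mostly_not_significant(self):
        rng = np.random.default_rng(5)
        n_units, B, T = 100, 60, 15
        attain = rng.normal(5.0, 0.5, size=(B, n_units, T))  # pure noise per realization
        gs = make_gs(np.zeros((n_units, T)), attain)
        calls = [linear_gap_trend(gs, u).significance for u in gs.unit_ids]
        assert np.mean([c == "none" for c in calls]) >= 0.85

    def test_insufficient_years_flagged(self):
        gs = make_gs(np.zeros((1, 5)), np.ones((1, 5)))
        assert linear_gap_trend(gs, "U0").insufficient


class TestTimeToClosure:
    def make_trend(self, x0, x1, spread=0.0):
        from yieldgap.trends import TrendResult

        x1s = np.array([x1 - spread, x1, x1 + spread])
        x0s = np.full(3, x0)
        sig = "negative" if x1 + spread < 0 else ("positive" if x1 - spread > 0 else "none")
        return TrendResult(unit_id="U0", x0=x0, x1=x1, x0s=x0s, x1s=x1s,
                           significance=sig, origin_year=1998)

    def test_closure_exactly_2010(self):
        cat, val = time_to_closure(self.make_trend(12.0, -1.0))
        assert cat == "years" and val == pytest.approx(0.0)

    def test_closure_2018(self):
        cat, val = time_to_closure(self.make_trend(4.0, -0.2))
        assert cat == "years" and val == pytest.approx(8.0)

    def test_mixed_sign_bounds_no_trend(self):
        cat, _ = time_to_closure(self.make_trend(4.0, -0.1, spread=0.3))
        assert cat == "no_trend"

    def test_growing_gap_widen(self):
        cat, val = time_to_closure(self.make_trend(4.0, 0.2))
        assert cat == "widen" and val < 0

    def test_analytic_crossing_through_machinery(self):
        t = np.arange(15)
        x0, x1 = 3.7, -0.25  # crossing at 1998 + 14.8 → t_close = 2.8
        gs = make_gs(np.zeros((1, 15)), np.tile(x0 + x1 * t, (2, 1, 1)))
        cat, val = time_to_closure(linear_gap_trend(gs, "U0"))
        assert cat == "years"
        assert val == pytest.approx(-x0 / x1 - 12.0, abs=1e-9)


class TestConservationAndAssembly:
    def test_gap_plus_actual_equals_attainable(self):
        cfg = ScenarioConfig(n_units=40, seed=1, year_start=1999, year_end=2001)
        rec, _, _ = generate_panel(cfg)
        spec = ModelSpec(("1", "gdd", "map", "irr"), protected=frozenset({"1"}))
        ens = {y: bootstrap_fit(rec, spec, y, B=3, seed=0) for y in (1999, 2000, 2001)}
        gs = gap_series_from_records(rec, ens)
        np.testing.assert_allclose(gs.gap + gs.actual[None, :, :], gs.attainable)
        assert gs.relative_gap_achieved.min() >= 0.0
        assert gs.relative_gap_achieved.max() <= 100.0


class TestAreaFraction:
    def grow_gs(self, slopes, areas, B=3, T=15):
        t = np.arange(T)
        U = len(slopes)
        attain = np.zeros((B, U, T))
        for u, s in enumerate(slopes):
            attain[:, u, :] = 2.0 + s * t
        area = np.tile(np.asarray(areas, float)[:, None], (1, T))
        return make_gs(np.zeros((U, T)), attain, area=area)

    def test_all_growing_is_100(self):
        gs = self.grow_gs([0.1, 0.2, 0.3], [1.0, 2.0, 3.0])
        frac = area_fraction_significant(gs, "gap", "increase", (1998, 2012), 2000)
        assert frac == pytest.approx(100.0)

    def test_none_significant_is_0(self):
        gs = self.grow_gs([0.0, 0.0], [1.0, 1.0])
        frac = area_fraction_significant(gs, "gap", "increase", (1998, 2012), 2000)
        assert frac == pytest.approx(0.0)

    def test_mixed_directions_partition_area(self):
        gs = self.grow_gs([0.2, -0.2, 0.0, 0.2], [1.0, 1.0, 1.0, 1.0])
        up = area_fraction_significant(gs, "gap", "increase", (1998, 2012), 2000)
        down = area_fraction_significant(gs, "gap", "decrease", (1998, 2012), 2000)
        assert up == pytest.approx(50.0)
        assert down == pytest.approx(25.0)
        assert up + down <= 100.0


class TestGlobalChange:
    def test_exact_one_percent_growth(self):
        t = np.arange(1996, 2013)
        T = len(t)
        base_2000 = 4.0
        gap = base_2000 * (1.0 + 0.01 * (t - 2000))
        gs = make_gs(np.zeros((1, T)), np.tile(gap, (3, 1, 1)), years=t)
        out = global_average_change(gs, "gap", (1998, 2012), base_year=2000)
        assert out["rate"] == pytest.approx(1.0, abs=1e-6)

    def test_constant_series_zero_rate_zero_width(self):
        t = np.arange(1996, 2013)
        gs = make_gs(np.zeros((1, len(t))), np.full((3, 1, len(t)), 5.0), years=t)
        out = global_average_change(gs, "gap", (1998, 2012))
        assert out["rate"] == pytest.approx(0.0, abs=1e-12)
        assert out["ci"][0] == pytest.approx(out["ci"][1])

    def test_near_zero_base_realization_rejected(self):
        t = np.arange(1996, 2013)
        T = len(t)
        attain = np.tile(4.0 + 0.04 * (t - 2000.0), (40, 1, 1))
        attain[7] = -1e-9  # this realization's gap is ≤ 0 at base year
        gs = make_gs(np.zeros((1, T)), attain, years=t)
        out = global_average_change(gs, "gap", (1998, 2012))
        assert out["n_rejected"] >= 1
        assert out["rate"] == pytest.approx(1.0, abs=1e-6)


class TestCounterfactual:
    def test_constant_areas_identical_arms(self):
        t = np.arange(2000, 2010)
        attain = np.tile(3.0 + 0.1 * (t - 2000), (2, 2, 1))
        gs = make_gs(np.zeros((2, len(t))), attain, area=np.full((2, len(t)), 7.0), years=t)
        out = fixed_area_counterfactual(gs, 2000)
        np.testing.assert_allclose(out["factual"], out["counterfactual"])

    def test_expansion_into_low_ceiling_unit(self):
        t = np.arange(2000, 2010)
        T = len(t)
        attain = np.zeros((1, 2, T))
        attain[:, 0, :] = 10.0  # high-ceiling unit, static area
        attain[:, 1, :] = 2.0  # low-ceiling unit, expanding area
        area = np.ones((2, T))
        area[1] = np.linspace(1.0, 50.0, T)
        gs = make_gs(np.zeros((2, T)), attain, area=area, years=t)
        out = fixed_area_counterfactual(gs, 2000)
        assert (out["factual"].iloc[1:] < out["counterfactual"].iloc[1:]).all()

    def test_single_unit_identical(self):
        t = np.arange(2000, 2006)
        attain = np.tile(np.linspace(3, 4, len(t)), (1, 1, 1))
        area = np.linspace(1, 2, len(t))[None, :]
        gs = make_gs(np.zeros((1, len(t))), attain, area=area, years=t)
        out = fixed_area_counterfactual(gs, 2000)
        np.testing.assert_allclose(out["factual"], out["counterfactual"])
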