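"""Foraging-threshold calibration, classification, dive stats and budgets."""

import numpy as np
import pytest

from deepdive.dive_segmentation import Dive, DiveMetrics
from deepdive.errors import CalibrationError, EmptyRecordError
from deepdive.foraging_budget import (
    calibrate_threshold,
    classify_foraging,
    foraging_dive_stats,
    time_budget,
)
from deepdive.tag_io import TagSeries


def _metric(dep, i, roll_var, has_clicks=None, pct_bottom=0.4, location="TestSite"):
    return DiveMetrics(dep, i, location, 500.0, 30.0, 1.2, 0.9, roll_var, 0.3, 1.0,
                       pct_bottom, has_clicks)


def _grid_oracle(rv, clicks, step=1e-4):
    """Exhaustive threshold scan (independent of the implementation)."""
    grid = np.arange(0.0, 1.0 + step, step)
    best_th, best_m = None, None
    for th in grid:
        m = int(np.sum(clicks & (rv <= th)) + np.sum(~clicks & (rv > th)))
        if best_m is None or m < best_m:
            best_th, best_m = th, m
    return best_th, best_m


class TestCalibration:
    def test_perfect_separation_zero_mismatch_at_gap_midpoint(self):
        rv = np.array([0.1, 0.15, 0.18, 0.55, 0.6, 0.7])
        clicks = np.array([False, False, False, True, True, True])
        model = calibrate_threshold(rv, clicks)
        assert model.n_mismatch == 0
        assert model.threshold == pytest.approx((0.18 + 0.55) / 2.0)
        assert model.confusion == {
            "click_forage": 3, "click_nonforage": 0,
            "silent_forage": 0, "silent_nonforage": 3,
        }

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_exhaustive_grid_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 60
        clicks = rng.random(n) < 0.5
        rv = np.clip(np.where(clicks, rng.normal(0.5, 0.18, n), rng.normal(0.25, 0.15, n)),
                     0.001, 0.999)
        model = calibrate_threshold(rv, clicks)
        th_o, m_o = _grid_oracle(rv, clicks)
        assert model.n_mismatch == m_o
        # identical induced classification
        np.testing.assert_array_equal(rv > model.threshold, rv > th_o)

    def test_inverted_labels_complement_the_mismatch_curve(self):
        rng = np.random.default_rng(9)
        clicks = rng.random(40) < 0.5
        rv = rng.uniform(0.05, 0.95, 40)
        m1 = calibrate_threshold(rv, clicks)
        m2 = calibrate_threshold(rv, ~clicks)
        merged = m1.curve.merge(m2.curve, on="threshold")
        assert (merged["mismatches_x"] + merged["mismatches_y"] == 40).all()

    def test_single_class_labels_rejected(self):
        with pytest.raises(CalibrationError):
            calibrate_threshold([0.2, 0.5], [True, True])

    def test_unlabelled_dives_ignored(self):
        rv = [0.1, 0.6, 0.9]
        model = calibrate_threshold(rv, [False, True, None])
        assert model.n_mismatch == 0


class TestClassification:
    def test_threshold_is_strict(self):
        metrics = [_metric("d", 0, 0.33), _metric("d", 1, 0.34)]
        labels = classify_foraging(metrics, 0.33)
        assert list(labels) == [False, True]

    def test_missing_bottom_metrics_are_non_foraging(self):
        labels = classify_foraging([_metric("d", 0, np.nan)], 0.1)
        assert list(labels) == [False]

    def test_generator_flags_recovered_on_clean_data(self, analysed_clean):
        metrics = analysed_clean["metrics"]
        truth = analysed_clean["truth"]
        model = calibrate_threshold(
            [m.roll_var_bottom for m in metrics], [m.has_clicks for m in metrics]
        )
        assert 0.15 < model.threshold < 0.6
        labels = classify_foraging(metrics, model.threshold)
        assert [bool(x) for x in labels] == [d.foraging for d in truth.dives]


class TestForagingDiveStats:
    def _dive(self, i, start, end, bottom):
        d = Dive("d0", i, start, end, 600.0, True)
        d.t_desc_end = start + (end - start - bottom) / 2.0
        d.t_asc_start = d.t_desc_end + bottom
        return d

    def test_worked_efficiency_example(self):
        # bottom 20 min, dive 40 min, next foraging dive starts 10 min later
        dives = [self._dive(0, 0.0, 2400.0, 1200.0), self._dive(1, 3000.0, 5400.0, 1200.0)]
        metrics = [_metric("d0", 0, 0.5, pct_bottom=0.5), _metric("d0", 1, 0.5, pct_bottom=0.5)]
        df = foraging_dive_stats(dives, metrics, [True, True])
        assert len(df) == 1  # last foraging dive excluded
        assert df["diving_efficiency"].iloc[0] == pytest.approx(1200.0 / 3000.0)

    def test_adjacent_dives_efficiency_equals_pct_bottom(self):
        dives = [self._dive(0, 0.0, 2400.0, 1200.0), self._dive(1, 2400.0, 4800.0, 1200.0)]
        metrics = [_metric("d0", 0, 0.5, pct_bottom=0.5), _metric("d0", 1, 0.5, pct_bottom=0.5)]
        df = foraging_dive_stats(dives, metrics, [True, True])
        assert df["diving_efficiency"].iloc[0] == pytest.approx(metrics[0].pct_bottom)

    def test_fewer_than_two_foraging_dives_gives_empty_table(self):
        dives = [self._dive(0, 0.0, 2400.0, 1200.0)]
        metrics = [_metric("d0", 0, 0.5)]
        df = foraging_dive_stats(dives, metrics, [True])
        assert df.empty and "diving_efficiency" in df.columns

    def test_non_foraging_dives_skipped_in_cycle(self):
        dives = [self._dive(0, 0.0, 1000.0, 400.0), self._dive(1, 1200.0, 2000.0, 300.0),
                 self._dive(2, 2500.0, 3500.0, 400.0)]
        metrics = [_metric("d0", i, 0.5) for i in range(3)]
        df = foraging_dive_stats(dives, metrics, [True, False, True])
        assert len(df) == 1
        assert df["diving_efficiency"].iloc[0] == pytest.approx(400.0 / 2500.0)


class TestTimeBudget:
    def _series(self, duration_s, fs=2.0):
        n = int(duration_s * fs) + 1
        t = np.arange(n) / fs
        accel = np.tile([0.0, 0.0, 9.81], (n, 1))
        mag = np.tile([0.26, 0.0, -0.96], (n, 1))
        return TagSeries("d0", "TestSite", fs, t, np.ones(n), accel, mag)

    def test_worked_budget_example(self):
        # one 30-min foraging dive with a 10-min bottom inside a 60-min record
        series = self._series(3600.0)
        d = Dive("d0", 0, 600.0, 2400.0, 600.0, True)
        d.t_desc_end, d.t_asc_start = 1200.0, 1800.0
        b = time_budget(series, [d], [True])
        assert b.pct_surface == pytest.approx(50.0)
        assert b.pct_foraging_dives == pytest.approx(50.0)
        assert b.pct_bottom_foraging == pytest.approx(100.0 / 6.0)

    def test_no_dives_is_all_surface(self):
        b = time_budget(self._series(1800.0), [], [])
        assert b.pct_surface == 100.0 and b.pct_foraging_dives == 0.0

    def test_surface_plus_dives_is_exactly_hundred(self, analysed_clean):
        series = analysed_clean["series"]
        dives = analysed_clean["dives"]
        labels = [True] * len(dives)
        b = time_budget(series, dives, labels)
        assert b.pct_surface + b.pct_all_dives == pytest.approx(100.0, abs=1e-9)
        assert b.pct_bottom_foraging <= b.pct_foraging_dives

    def test_zero_length_record_rejected(self):
        series = self._series(10.0)
        series.segment_bounds = [(0, 1)]
        with pytest.raises(EmptyRecordError):
            time_budget(series, [], [])


def test_budgets_invariant_to_sampling_rate():
    """The dive plan is fs-independent, so budgets at 16 vs 32 Hz agree
    within half a percentage point."""
    from conftest import MINI_MIXTURE, MINI_SPECS
    from deepdive import synthetic_data as sd
    from deepdive.pipeline import analyse_deployment
    from deepdive.tag_io import RunConfig

    budgets = {}
    for fs in (16.0, 32.0):
        series, _ = sd.simulate_deployment(
            MINI_SPECS, MINI_MIXTURE, 3, fs=fs, seed=77,
            lead_in_s=90.0, surface_median_s=120.0, noise=0.0,
        )
        res = analyse_deployment(series, RunConfig(trim_min=1.0))
        labels = classify_foraging(res["metrics"], 0.33)
        budgets[fs] = time_budget(res["series"], res["dives"], labels)
    for attr in ("pct_surface", "pct_foraging_dives", "pct_bottom_foraging"):
        assert abs(getattr(budgets[16.0], attr) - getattr(budgets[32.0], attr)) < 0.5
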