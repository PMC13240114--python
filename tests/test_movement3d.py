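"""Dead reckoning, tortuosity, depth-band profiles and gyration detection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from deepdive.dive_segmentation import Dive, detect_dives, segment_phases
from deepdive.errors import UndefinedStatisticError
from deepdive.kinematics import OrientationSeries, estimate_orientation
from deepdive.movement3d import (
    band_profiles,
    dead_reckon,
    detect_gyrations,
    tortuosity_index,
)


def _orientation(pitch, roll, heading, fs=10.0):
    n = len(pitch)
    return OrientationSeries(np.arange(n) / fs, np.asarray(pitch, float),
                             np.asarray(roll, float), np.asarray(heading, float), fs)


class TestDeadReckon:
    def test_level_northward_track(self):
        fs, dur = 10.0, 10.0
        n = int(dur * fs)
        ori = _orientation(np.zeros(n), np.zeros(n), np.zeros(n), fs)
        tr = dead_reckon(ori, np.zeros(n), speed=2.0)
        assert tr.x[-1] == pytest.approx(0.0, abs=1e-9)
        assert tr.y[-1] == pytest.approx(2.0 * (n - 1) / fs, abs=1e-9)

    def test_vertical_descent_has_no_horizontal_displacement(self):
        n = 100
        ori = _orientation(np.full(n, -np.pi / 2), np.zeros(n), np.zeros(n))
        tr = dead_reckon(ori, np.linspace(0, 200, n), speed=2.0)
        assert np.allclose(tr.x, 0.0, atol=1e-9) and np.allclose(tr.y, 0.0, atol=1e-9)

    def test_full_circle_closes(self):
        # n+1 samples: the closed polygon needs n steps over n uniform headings
        fs, n = 32.0, 1920
        heading = 2 * np.pi * np.arange(n + 1) / n
        ori = _orientation(np.zeros(n + 1), np.zeros(n + 1), heading, fs)
        tr = dead_reckon(ori, np.zeros(n + 1), speed=2.0)
        path = np.sum(np.hypot(np.diff(tr.x), np.diff(tr.y)))
        closure = np.hypot(tr.x[-1], tr.y[-1])
        assert closure < 1e-6 * path

    def test_net_displacement_bounded_by_speed_times_duration(self, clean_deployment):
        series, _ = clean_deployment
        ori = estimate_orientation(series, smooth_s=0.5)
        tr = dead_reckon(ori, series.depth, speed=2.0)
        net = np.hypot(tr.x[-1], tr.y[-1])
        assert net <= 2.0 * (series.t[-1] - series.t[0]) + 1e-6


class TestTortuosity:
    def test_straight_segment_is_zero(self):
        x = np.linspace(0, 100, 50)
        assert tortuosity_index(x, np.zeros(50)) == pytest.approx(0.0, abs=1e-12)

    def test_closed_circle_is_one(self):
        th = np.linspace(0, 2 * np.pi, 721)
        assert tortuosity_index(np.cos(th), np.sin(th)) == pytest.approx(1.0, abs=1e-9)

    def test_semicircle_analytic_value(self):
        # net = 2r, path = pi r  ->  TI = 1 - 2/pi
        th = np.linspace(0, np.pi, 2001)
        ti = tortuosity_index(np.cos(th), np.sin(th))
        assert ti == pytest.approx(1.0 - 2.0 / np.pi, abs=1e-3)

    def test_stationary_segment_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            tortuosity_index(np.zeros(10), np.zeros(10))

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.floats(-np.pi, np.pi))
    def test_bounded_and_rotation_invariant(self, seed, phi):
        rng = np.random.default_rng(seed)
        steps = rng.normal(size=(30, 2))
        xy = np.cumsum(steps, axis=0)
        ti = tortuosity_index(xy[:, 0], xy[:, 1])
        assert 0.0 <= ti <= 1.0
        c, s = np.cos(phi), np.sin(phi)
        xr = c * xy[:, 0] - s * xy[:, 1]
        yr = s * xy[:, 0] + c * xy[:, 1]
        assert tortuosity_index(xr, yr) == pytest.approx(ti, abs=1e-9)


class TestBandProfiles:
    def test_monotone_descent_counts_bands(self):
        fs = 2.0
        n = 800
        t = np.arange(n) / fs
        depth = np.r_[np.linspace(0.5, 200.0, 400), np.linspace(200.0, 0.5, 400)]
        pitch = np.r_[np.full(400, -0.7), np.full(400, 0.7)]
        heading = 0.002 * np.arange(n)
        ori = OrientationSeries(t, pitch, np.zeros(n), heading, fs)
        from deepdive.tag_io import TagSeries

        accel = np.tile([0.0, 0.0, 9.81], (n, 1))
        mag = np.tile([0.26, 0.0, -0.96], (n, 1))
        series = TagSeries("b", "loc", fs, t, depth, accel, mag)
        d = Dive("b", 0, t[4], t[-5], 200.0, True)
        d.t_desc_end = d.t_asc_start = t[400]
        tr = dead_reckon(ori, depth)
        profiles = band_profiles(series, ori, tr, [d], 50.0)
        desc = [p for p in profiles if p.phase == "descent"]
        assert [int(p.band_lo) for p in desc] == [0, 50, 100, 150]

    def test_band_union_covers_in_dive_samples_once(self, analysed_clean):
        series = analysed_clean["series"]
        ori = analysed_clean["orientation"]
        tr = dead_reckon(ori, series.depth)
        profiles = band_profiles(series, ori, tr, analysed_clean["dives"], 50.0,
                                 min_samples=1)
        t = series.t
        for d in analysed_clean["dives"]:
            n_desc = np.count_nonzero((t >= d.start_s) & (t < d.t_desc_end))
            got = sum(p.n_samples for p in profiles
                      if p.dive_id == d.dive_id and p.phase == "descent")
            assert got == n_desc

    def test_elevated_roll_band_detected(self):
        fs = 2.0
        n = 1200
        t = np.arange(n) / fs
        depth = np.r_[np.linspace(0.5, 300.0, 600), np.linspace(300.0, 0.5, 600)]
        pitch = np.r_[np.full(600, -0.7), np.full(600, 0.7)]
        roll = np.zeros(n)
        rng = np.random.default_rng(0)
        in_band = (depth >= 100.0) & (depth < 150.0) & (pitch < 0)
        roll[in_band] = rng.normal(0.0, 1.2, in_band.sum())
        ori = OrientationSeries(t, pitch, roll, 0.002 * np.arange(n), fs)
        from deepdive.tag_io import TagSeries

        accel = np.tile([0.0, 0.0, 9.81], (n, 1))
        mag = np.tile([0.26, 0.0, -0.96], (n, 1))
        series = TagSeries("b", "loc", fs, t, depth, accel, mag)
        d = Dive("b", 0, t[2], t[-3], 300.0, True)
        d.t_desc_end = d.t_asc_start = t[600]
        profiles = band_profiles(series, ori, dead_reckon(ori, depth), [d], 50.0)
        desc = {int(p.band_lo): p.roll_var for p in profiles if p.phase == "descent"}
        assert desc[100] > 5 * max(desc[0], desc[50], desc[150], 1e-6)


class TestGyrations:
    def _dive_with_spans(self, n, fs):
        t = np.arange(n) / fs
        d = Dive("g", 0, t[0], t[-1], 500.0, True)
        d.t_desc_end = t[n // 2]
        d.t_asc_start = t[n // 2]
        return d, t

    def test_injected_rotations_recovered_exactly(self):
        from deepdive.synthetic_data import inject_gyration

        fs, n = 16.0, 4800
        for n_rot, direction in ((2, 1), (3, -1), (5, 1)):
            roll = 0.05 * np.sin(np.arange(n) / 200.0)
            roll, ev = inject_gyration(roll, 400, n_rot, direction, int(fs * 9))
            d, t = self._dive_with_spans(n, fs)
            ori = OrientationSeries(t, np.zeros(n), roll, np.zeros(n), fs)
            events = detect_gyrations(ori, [d])
            assert len(events) == 1
            assert events[0].n_rotations == n_rot
            assert events[0].direction == direction
            assert events[0].phase == "descent" and events[0].axis == "roll"

    def test_single_turn_is_below_minimum(self):
        fs, n = 16.0, 2000
        roll = np.unwrap(np.linspace(0, 2 * np.pi, n))
        d, t = self._dive_with_spans(n, fs)
        ori = OrientationSeries(t, np.zeros(n), roll, np.zeros(n), fs)
        assert detect_gyrations(ori, [d]) == []

    def test_constant_angle_gives_no_event(self):
        fs, n = 16.0, 2000
        d, t = self._dive_with_spans(n, fs)
        ori = OrientationSeries(t, np.zeros(n), np.full(n, 0.3), np.zeros(n), fs)
        assert detect_gyrations(ori, [d]) == []

    def test_ascent_heading_pairing(self):
        from deepdive.synthetic_data import inject_gyration

        fs, n = 16.0, 4800
        heading = np.zeros(n)
        heading, _ = inject_gyration(heading, n // 2 + 200, 2, 1, int(fs * 9))
        d, t = self._dive_with_spans(n, fs)
        ori = OrientationSeries(t, np.zeros(n), np.zeros(n), heading, fs)
        events = detect_gyrations(ori, [d])
        assert len(events) == 1 and events[0].phase == "ascent" and events[0].axis == "heading"

    def test_generator_round_trip_on_clean_deployment(self, analysed_clean):
        truth = analysed_clean["truth"]
        events = detect_gyrations(analysed_clean["orientation"], analysed_clean["dives"])
        got = sorted((e.phase, e.axis, e.n_rotations, e.direction) for e in events)
        expected = sorted((g.phase, g.axis, g.n_rotations, g.direction) for g in truth.gyrations)
        assert got == expected
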