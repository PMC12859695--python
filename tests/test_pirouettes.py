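import math
from dataclasses import replace

import numpy as np
import pytest

from wormassay import (
    ELEGANS_LIKE, detect_pirouettes, heading_series, pirouette_rate,
    simulate_track,
)
from wormassay.pirouettes import wrap_degrees
from wormassay.errors import InsufficientDataError

from conftest import make_track
from oracles import brute_force_pirouettes


def path_from_steps(headings_deg, step_lengths):
    """Build centroid positions from per-step headings and lengths."""
    rad = np.deg2rad(np.asarray(headings_deg, float))
    steps = np.column_stack([np.cos(rad), np.sin(rad)]) \
        * np.asarray(step_lengths, float)[:, None]
    return np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])


def turn_track(dt=0.1):
    """10 s of eastward cruising at 0.3 mm/s, then a 150-degree net turn
    over 2 s during which speed drops to 0.08 mm/s, then cruising on the
    new heading."""
    pre = 100   # 10 s
    turn = 20   # 2 s
    post = 50   # 5 s
    headings = ([0.0] * pre
                + list(np.linspace(7.5, 150.0, turn))
                + [150.0] * post)
    lengths = [0.03] * pre + [0.008] * turn + [0.03] * post
    return make_track(path_from_steps(headings, lengths), dt=dt)


class TestHeadingSeries:
    def test_eastward_increments_zero(self, straight_track):
        hs = heading_series(straight_track)
        assert np.allclose(hs.headings, 0.0)
        assert np.allclose(hs.turn_increments[1:], 0.0)

    def test_wrap_rule(self):
        # heading 170 then -170 is a +20 increment, not -340
        tr = make_track(path_from_steps([170.0, -170.0], [0.05, 0.05]))
        hs = heading_series(tr)
        assert hs.turn_increments[1] == pytest.approx(20.0)
        assert wrap_degrees(-340.0) == pytest.approx(20.0)

    def test_sub_floor_jitter_masked(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(0, 0.001, size=(50, 2))  # jitter << min_step
        hs = heading_series(make_track(pts))
        assert np.all(np.isnan(hs.headings))

    def test_gap_masks_spans(self):
        tr = make_track([[0, 0], [1, 0], [2, 0], [3, 0]],
                        valid=[True, False, True, True])
        hs = heading_series(tr)
        assert np.isnan(hs.headings[0]) and np.isnan(hs.headings[1])
        assert hs.headings[2] == pytest.approx(0.0)

    def test_too_few_frames(self):
        with pytest.raises(InsufficientDataError):
            heading_series(make_track([[0, 0], [1, 0]]))


class TestDetect:
    def test_constant_heading_no_events(self):
        x = np.arange(200) * 0.03
        tr = make_track(np.column_stack([x, np.zeros_like(x)]))
        assert detect_pirouettes(tr, resample_dt=None) == []

    def test_single_injected_turn_detected(self):
        tr = turn_track()
        events = detect_pirouettes(tr, resample_dt=None, min_step=0.005)
        assert len(events) == 1
        (e,) = events
        assert abs(e.net_turn) > 120.0
        assert e.net_turn == pytest.approx(150.0, abs=20.0)
        assert e.speed_drop >= 0.40
        assert 9.0 <= e.t_start <= 11.0

    def test_turn_without_speed_drop_not_an_event(self):
        """The criterion is conjunctive: angle alone is insufficient."""
        headings = [0.0] * 100 + list(np.linspace(7.5, 150.0, 20)) + [150.0] * 50
        lengths = [0.03] * 170  # constant speed throughout
        tr = make_track(path_from_steps(headings, lengths))
        assert detect_pirouettes(tr, resample_dt=None) == []

    def test_short_track_raises(self):
        with pytest.raises(InsufficientDataError):
            detect_pirouettes(make_track(np.zeros((30, 2))))

    def test_matches_bruteforce_oracle(self):
        """Windowed detection equals the exhaustive sub-interval scan
        (after merging) on mixed synthetic tracks."""
        for seed in range(8):
            p = replace(ELEGANS_LIKE, pirouette_rate=1.0, gap_prob=0.03,
                        noise_sd=0.005)
            tr = simulate_track(p, 120, 0.1, seed=seed)
            got = detect_pirouettes(tr)
            hs = heading_series(tr, resample_dt=0.5)
            expected = brute_force_pirouettes(hs)
            assert len(got) == len(expected)
            for g, (t0, t1, net, vmean, bmean) in zip(got, expected):
                assert g.t_start == pytest.approx(t0)
                assert g.t_end == pytest.approx(t1)
                assert g.net_turn == pytest.approx(net)
                assert g.event_speed == pytest.approx(vmean)
                assert g.baseline_speed == pytest.approx(bmean)

    def test_threshold_monotonicity(self):
        """Lowering either threshold never decreases the event count."""
        tr = simulate_track(replace(ELEGANS_LIKE, pirouette_rate=1.5,
                                    gap_prob=0.0), 300, 0.1, seed=21)
        base = len(detect_pirouettes(tr))
        assert len(detect_pirouettes(tr, angle_threshold=90.0)) >= base
        assert len(detect_pirouettes(tr, drop_threshold=0.2)) >= base

    def test_rotation_invariance_and_reflection_sign(self):
        tr = turn_track()
        events = detect_pirouettes(tr, resample_dt=None, min_step=0.005)
        ang = np.deg2rad(73.0)
        rot = np.array([[np.cos(ang), -np.sin(ang)],
                        [np.sin(ang), np.cos(ang)]])
        tr_rot = make_track(tr.centroid @ rot.T)
        ev_rot = detect_pirouettes(tr_rot, resample_dt=None, min_step=0.005)
        tr_ref = make_track(tr.centroid * np.array([1.0, -1.0]))
        ev_ref = detect_pirouettes(tr_ref, resample_dt=None, min_step=0.005)
        assert len(ev_rot) == len(ev_ref) == len(events)
        for e, er, ef in zip(events, ev_rot, ev_ref):
            assert er.t_start == pytest.approx(e.t_start)
            assert er.net_turn == pytest.approx(e.net_turn, abs=1e-6)
            assert ef.net_turn == pytest.approx(-e.net_turn, abs=1e-6)

    def test_absolute_mode_fires_on_oscillation_net_does_not(self):
        """Zig-zag wiggling accumulates |increments| without net
        reorientation; only the 'absolute' cumulative mode treats it as
        turning (motivating 'net' as the default)."""
        headings = [0.0] * 100 + [45.0, -45.0] * 10 + [0.0] * 50
        lengths = [0.03] * 100 + [0.008] * 20 + [0.03] * 50
        tr = make_track(path_from_steps(headings, lengths))
        assert detect_pirouettes(tr, resample_dt=None, min_step=0.005) == []
        assert len(detect_pirouettes(tr, resample_dt=None, min_step=0.005,
                                     mode="absolute")) >= 1


class TestRate:
    def test_zero_events_zero_rate(self):
        tr = simulate_track(replace(ELEGANS_LIKE, pirouette_rate=0.0,
                                    gap_prob=0.0), 60, 0.1, seed=2)
        s = pirouette_rate(tr, [])
        assert s.rate == 0.0
        assert s.observed_minutes == pytest.approx(1.0)

    def test_rate_arithmetic(self):
        tr = simulate_track(replace(ELEGANS_LIKE, pirouette_rate=0.0,
                                    gap_prob=0.0), 1800, 0.1, seed=3)
        events = [object()] * 6  # six events over 30 valid minutes
        assert pirouette_rate(tr, events).rate == pytest.approx(0.2)

    def test_observed_minutes_counts_valid_time_only(self):
        tr = simulate_track(replace(ELEGANS_LIKE, pirouette_rate=0.0,
                                    gap_prob=0.5), 60, 0.1, seed=4)
        s = pirouette_rate(tr, [])
        assert s.observed_minutes < 0.5
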