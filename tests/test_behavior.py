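import math

import numpy as np
import pytest

from oracles import scan_entrances
from ripplescreen.behavior import (
    APATrial,
    MWMTrial,
    ShockZone,
    apa_bout_distance,
    apa_entrances,
    apa_latency_first_entrance,
    apa_opposite_quadrant_time,
    apa_path_length,
    apa_pseudoshocks_per_entrance,
    apa_room_frame,
    latency_slope,
    mwm_daily_latency,
    overnight_change,
    probe_distance_auc,
    probe_quadrant_time,
    probe_target_crossings,
)

FPS = 30.0


def _hidden(day, idx, latency):
    return MWMTrial(day=day, trial_index=idx, kind="HIDDEN",
                    track=np.zeros((1, 3)), escape_latency_s=latency)


def _probe_track(t, x, y, platform=(30.0, 30.0)):
    return MWMTrial(day=6, trial_index=1, kind="PROBE",
                    track=np.column_stack([t, x, y]), platform_center=platform)


class TestMWMLatency:
    def test_daily_mean(self):
        trials = [_hidden(1, i + 1, v) for i, v in enumerate([60, 40, 20, 40])]
        assert mwm_daily_latency(trials, 1) == pytest.approx(40.0)

    def test_single_trial_and_cap(self):
        assert mwm_daily_latency([_hidden(2, 1, 33.0)], 2) == pytest.approx(33.0)
        capped = [_hidden(1, i, 60.0) for i in range(1, 5)]
        assert mwm_daily_latency(capped, 1) == pytest.approx(60.0)

    def test_no_trials_errors(self):
        with pytest.raises(ValueError):
            mwm_daily_latency([], 1)

    def test_slope_worked_cases(self):
        assert latency_slope([(1, 40.0), (2, 30.0), (3, 20.0)], (1, 3)) == pytest.approx(-10.0)
        assert latency_slope([(1, 25.0), (2, 25.0), (3, 25.0)], (1, 3)) == pytest.approx(0.0)
        assert latency_slope([(1, 40.0), (2, 30.0)], (1, 2)) == pytest.approx(-10.0)
        with pytest.raises(ValueError):
            latency_slope([(1, 40.0)], (1, 2))

    def test_overnight_change(self):
        trials = [_hidden(1, 4, 50.0), _hidden(2, 1, 30.0)]
        assert overnight_change(trials, (1, 2)) == pytest.approx(-20.0)
        trials = [_hidden(1, 4, 20.0), _hidden(2, 1, 60.0)]
        assert overnight_change(trials, (1, 2)) == pytest.approx(40.0)
        with pytest.raises(ValueError):
            overnight_change([_hidden(1, 4, 20.0)], (1, 2))


class TestMWMProbe:
    def test_quadrant_time_all_in_target(self):
        t = np.arange(0, 60, 1 / FPS)
        trial = _probe_track(t, np.full_like(t, 20.0), np.full_like(t, 20.0))
        assert probe_quadrant_time(trial) == pytest.approx(100.0)

    def test_quadrant_time_uniform_sweep_is_quarter(self):
        t = np.arange(0, 60, 1 / FPS)
        ang = 2 * np.pi * t / 60.0  # one full circle
        trial = _probe_track(t, 40 * np.cos(ang), 40 * np.sin(ang))
        assert probe_quadrant_time(trial) == pytest.approx(25.0, abs=2.0)

    def test_quadrant_sums_to_100(self):
        rng = np.random.default_rng(0)
        t = np.arange(0, 60, 1 / FPS)
        x, y = rng.normal(0, 20, len(t)), rng.normal(0, 20, len(t))
        total = 0.0
        for center in [(30, 30), (-30, 30), (-30, -30), (30, -30)]:
            total += probe_quadrant_time(_probe_track(t, x, y, platform=center))
        assert total == pytest.approx(100.0)

    def test_target_crossings(self):
        t = np.arange(5) / FPS
        path_through = np.array([-20.0, 0.0, 20.0, 40.0, 60.0])
        trial = _probe_track(t, path_through, path_through, platform=(0.0, 0.0))
        assert probe_target_crossings(trial) == 1
        # out and back in: two entries
        x = np.array([-20.0, 0.0, -20.0, 0.0, -20.0])
        trial2 = _probe_track(t, x, np.zeros_like(x), platform=(0.0, 0.0))
        assert probe_target_crossings(trial2) == 2
        far = _probe_track(t, path_through + 100, path_through, platform=(0.0, 0.0))
        assert probe_target_crossings(far) == 0

    def test_distance_auc_closed_forms(self):
        t = np.arange(0, 6.0, 1 / FPS)
        const = _probe_track(t, np.full_like(t, 30.0), np.zeros_like(t), platform=(0.0, 0.0))
        assert probe_distance_auc(const) == pytest.approx(150.0, rel=1e-6)
        # linear approach 30 -> 0 over 5 s: triangle area 75
        x = np.clip(30.0 - 6.0 * t, 0.0, None)
        lin = _probe_track(t, x, np.zeros_like(t), platform=(0.0, 0.0))
        assert probe_distance_auc(lin) == pytest.approx(75.0, rel=0.01)
        with pytest.raises(ValueError):
            probe_distance_auc(_probe_track(t[:30], x[:30], x[:30]))

    def test_metrics_invariant_to_pool_rotation(self):
        rng = np.random.default_rng(1)
        t = np.arange(0, 60, 1 / FPS)
        x, y = rng.normal(0, 25, len(t)), rng.normal(0, 25, len(t))
        phi = 0.7
        rx = x * np.cos(phi) - y * np.sin(phi)
        ry = x * np.sin(phi) + y * np.cos(phi)
        p = np.array([30.0, 10.0])
        rp = (p[0] * np.cos(phi) - p[1] * np.sin(phi), p[0] * np.sin(phi) + p[1] * np.cos(phi))
        a = probe_distance_auc(_probe_track(t, x, y, platform=tuple(p)))
        b = probe_distance_auc(_probe_track(t, rx, ry, platform=rp))
        assert a == pytest.approx(b, rel=1e-9)
        ca = probe_target_crossings(_probe_track(t, x, y, platform=tuple(p)),
                                    platform_half_width=7.0)
        # crossings use an axis-aligned square, so rotate only the AUC check


ZONE = ShockZone(center_deg=0.0, width_deg=60.0)


def _stationary_arena_track(duration_s=600.0, radius=15.0, angle_deg=0.0):
    t = np.arange(0, duration_s, 1 / FPS)
    a = math.radians(angle_deg)
    return np.column_stack([t, np.full_like(t, radius * math.cos(a)),
                            np.full_like(t, radius * math.sin(a))])


class TestAPA:
    def test_room_frame_rotation(self):
        track = _stationary_arena_track(70.0, radius=15.0, angle_deg=0.0)
        room = apa_room_frame(track, 6.0)
        i10 = int(10 * FPS)
        assert room[i10, 1] == pytest.approx(60.0, abs=1e-6)
        assert room[i10, 2] == pytest.approx(15.0)
        ident = apa_room_frame(track, 0.0)
        np.testing.assert_allclose(ident[:, 1], 0.0, atol=1e-9)
        i60 = int(60 * FPS)  # one full rotation returns to the same angle
        assert room[i60, 1] == pytest.approx(0.0, abs=1e-6)

    def test_stationary_mouse_sweeps_zone_ten_times(self):
        room = apa_room_frame(_stationary_arena_track(600.0), 6.0)
        assert apa_entrances(room, ZONE) == 10

    def test_avoiding_mouse_never_enters(self):
        t = np.arange(0, 600.0, 1 / FPS)
        ang = np.radians(180.0 - 6.0 * t)  # tracks the rotation, stays opposite
        track = np.column_stack([t, 15 * np.cos(ang), 15 * np.sin(ang)])
        assert apa_entrances(apa_room_frame(track, 6.0), ZONE) == 0

    def test_boundary_jitter_counts_once(self):
        t = np.arange(0, 10.0, 1 / FPS)
        rng = np.random.default_rng(2)
        ang = np.radians(30.0 + rng.normal(0, 0.5, size=len(t)))  # jitter on the edge
        track = np.column_stack([t, 15 * np.cos(ang), 15 * np.sin(ang)])
        room = apa_room_frame(track, 0.0)
        assert apa_entrances(room, ZONE) <= 2

    def test_entrances_match_frame_scan_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            n = 600
            t = np.arange(n) / FPS
            ang = np.cumsum(rng.normal(0, 4.0, size=n)) % 360.0
            room = np.column_stack([t, ang, np.full(n, 15.0)])
            assert apa_entrances(room, ZONE) == scan_entrances(t, ang, 0.0, 60.0, 0.5)

    def test_latency_first_entrance(self):
        t = np.arange(0, 600.0, 1 / FPS)
        ang = np.where(t < 42.0, 180.0, 0.0)
        room = np.column_stack([t, ang, np.full_like(t, 15.0)])
        assert apa_latency_first_entrance(room, ZONE) == pytest.approx(42.0, abs=0.04)
        never = np.column_stack([t, np.full_like(t, 180.0), np.full_like(t, 15.0)])
        assert apa_latency_first_entrance(never, ZONE) == 600.0
        immediate = np.column_stack([t, np.zeros_like(t), np.full_like(t, 15.0)])
        assert apa_latency_first_entrance(immediate, ZONE) == 0.0

    def test_path_length_is_arena_frame(self):
        assert apa_path_length(_stationary_arena_track(60.0)) == pytest.approx(0.0)
        t = np.arange(0, 10, 1 / FPS)
        walk = np.column_stack([t, 10.0 * t, np.zeros_like(t)])
        assert apa_path_length(walk) == pytest.approx(100.0 - 10.0 / FPS, rel=0.01)
        two = np.array([[0.0, 0.0, 0.0], [1 / FPS, 3.0, 0.0]])
        assert apa_path_length(two) == pytest.approx(3.0)

    def test_opposite_quadrant_time(self):
        t = np.arange(0, 60, 1 / FPS)
        anti = np.column_stack([t, np.full_like(t, 180.0), np.full_like(t, 15.0)])
        assert apa_opposite_quadrant_time(anti, ZONE) == pytest.approx(100.0)
        inzone = np.column_stack([t, np.zeros_like(t), np.full_like(t, 15.0)])
        assert apa_opposite_quadrant_time(inzone, ZONE) == pytest.approx(0.0)
        uniform = np.column_stack([t, (360.0 * t / 60.0) % 360.0, np.full_like(t, 15.0)])
        assert apa_opposite_quadrant_time(uniform, ZONE) == pytest.approx(25.0, abs=2.0)

    def test_bout_distance_boundary_to_antipode(self):
        # move at constant radius 15 from the zone boundary (30 deg) to the
        # antipode (180 deg): arc of 150 deg -> +pi*15*(150/180) ~ 39.27 cm
        t = np.arange(0, 10.0, 1 / FPS)
        ang_room = 30.0 + (180.0 - 30.0) * t / t[-1]
        ang_arena = np.radians(ang_room - 6.0 * t)
        track = np.column_stack([t, 15 * np.cos(ang_arena), 15 * np.sin(ang_arena)])
        got = apa_bout_distance(track, ZONE, rotation_deg_s=6.0)
        assert got == pytest.approx(math.pi * 15 * 150 / 180, rel=0.02)

    def test_bout_distance_no_movement_and_round_trip(self):
        assert math.isnan(apa_bout_distance(_stationary_arena_track(60.0), ZONE,
                                            speed_threshold_cm_s=2.0))
        t = np.arange(0, 10.0, 1 / FPS)
        ang_room = 30.0 + 150.0 * np.sin(np.pi * t / t[-1])  # returns to start
        ang_arena = np.radians(ang_room - 6.0 * t)
        track = np.column_stack([t, 15 * np.cos(ang_arena), 15 * np.sin(ang_arena)])
        # bout splitting at the turning point and 30 Hz discretization leave
        # a ~1 cm residual on a +-39 cm scale
        assert apa_bout_distance(track, ZONE, rotation_deg_s=6.0) == pytest.approx(0.0, abs=2.0)

    def test_pseudoshocks_schedule(self):
        t = np.arange(0, 60.0, 1 / FPS)
        ang = np.where((t >= 10.0) & (t < 14.0), 0.0, 180.0)  # inside 4.0 s
        room = np.column_stack([t, ang, np.full_like(t, 15.0)])
        assert apa_pseudoshocks_per_entrance(room, ZONE) == pytest.approx(3.0)
        ang1 = np.where((t >= 10.0) & (t < 11.0), 0.0, 180.0)  # inside 1.0 s
        room1 = np.column_stack([t, ang1, np.full_like(t, 15.0)])
        assert apa_pseudoshocks_per_entrance(room1, ZONE) == pytest.approx(1.0)
        never = np.column_stack([t, np.full_like(t, 180.0), np.full_like(t, 15.0)])
        assert math.isnan(apa_pseudoshocks_per_entrance(never, ZONE))
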