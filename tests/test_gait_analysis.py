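"""Velocity profiles, event detection and gait parameters."""

import numpy as np
import pytest

from gaitlidar.gait_analysis import (
    GaitEvent,
    VelocityProfile,
    compute_parameters,
    detect_events,
    filter_profile,
    heel_strikes,
    velocity_profile,
)
from gaitlidar.leg_tracking import LegObservation, LegTrack


def make_track(positions_left, positions_right, rate=40.0):
    def obs(seq):
        return [
            LegObservation(i / rate, np.asarray(p, dtype=float), 20, "observed")
            for i, p in enumerate(seq)
        ]
    return LegTrack(left=obs(positions_left), right=obs(positions_right))


def profile_from_speed(speed, rate=40.0, leg="left"):
    speed = np.asarray(speed, dtype=float)
    t = (np.arange(speed.size) + 0.5) / rate
    p = VelocityProfile(leg, t, speed)
    p.filtered = speed.copy()
    p.positions = np.zeros((speed.size + 1, 2))
    p.t_track = np.arange(speed.size + 1) / rate
    return p


class TestVelocityProfile:
    def test_stationary_all_zero(self):
        pos = [(1.0, 2.0)] * 10
        left, right = velocity_profile(make_track(pos, pos))
        assert np.all(left.speed == 0)

    def test_uniform_motion_constant_speed(self):
        pos = [(0.025 * i, 0.0) for i in range(20)]  # 1 m/s at 40 Hz
        left, _ = velocity_profile(make_track(pos, pos))
        np.testing.assert_allclose(left.speed, 100.0, rtol=1e-9)

    def test_sinusoid_peak_speed(self):
        rate, A, omega = 40.0, 0.5, 2 * np.pi * 1.0
        t = np.arange(0, 2.0, 1 / rate)
        pos = [(A * np.sin(omega * ti), 0.0) for ti in t]
        left, _ = velocity_profile(make_track(pos, pos), rate=rate)
        assert left.speed.max() == pytest.approx(A * omega * 100, rel=0.02)

    def test_single_frame_error(self):
        with pytest.raises(ValueError):
            velocity_profile(make_track([(0, 0)], [(0, 0)]))


class TestFilterProfile:
    def test_constant_unchanged(self):
        p = profile_from_speed(np.full(50, 80.0))
        filter_profile(p)
        np.testing.assert_allclose(p.filtered, 80.0)

    def test_spike_removed(self):
        speed = np.full(50, 100.0)
        speed[25] = 500.0
        p = profile_from_speed(speed)
        filter_profile(p, windows=(5, 1))
        assert p.filtered[25] == pytest.approx(100.0)

    def test_unit_windows_identity(self):
        speed = np.arange(30, dtype=float)
        p = profile_from_speed(speed)
        filter_profile(p, windows=(1, 1))
        np.testing.assert_allclose(p.filtered, speed)

    def test_even_window_error(self):
        p = profile_from_speed(np.zeros(10))
        with pytest.raises(ValueError):
            filter_profile(p, windows=(4, 9))


def swing_profile(n_bumps, rate=40.0, peak=200.0, bump_len=16, gap_len=24):
    """Alternating stance (0) and raised-cosine swing bumps."""
    parts = [np.zeros(gap_len)]
    for _ in range(n_bumps):
        phase = np.linspace(0, 1, bump_len)
        parts.append(peak * 0.5 * (1 - np.cos(2 * np.pi * phase)))
        parts.append(np.zeros(gap_len))
    return np.concatenate(parts)


class TestDetectEvents:
    def test_quiet_profile_single_valley(self):
        p = profile_from_speed(np.zeros(40))
        events = detect_events(p)
        valleys = [e for e in events if e.kind == "valley"]
        peaks = [e for e in events if "peak" in e.kind]
        assert len(valleys) == 1 and not peaks
        assert valleys[0].t_start == pytest.approx(p.t[0])
        assert valleys[0].t_end == pytest.approx(p.t[-1])

    def test_ten_bumps_ten_major_peaks(self):
        p = profile_from_speed(swing_profile(10))
        events = detect_events(p)
        majors = [e for e in events if e.kind == "major_peak"]
        assert len(majors) == 10

    def test_minor_peaks_between_majors(self):
        speed = swing_profile(2, gap_len=40)
        # a 20 cm/s ankle bump inside the second stance
        speed[16 + 40 + 16 + 10 : 16 + 40 + 16 + 18] = 20.0
        p = profile_from_speed(speed)
        events = detect_events(p)
        minors = [e for e in events if e.kind == "minor_peak"]
        assert len(minors) == 1

    def test_unfiltered_profile_rejected(self):
        p = profile_from_speed(np.zeros(10))
        p.filtered = None
        with pytest.raises(ValueError):
            detect_events(p)


class TestHeelStrikes:
    def test_valley_median_timestamp(self):
        # valley spanning t = 1.0 ... 1.4 s after a major peak
        rate = 40.0
        speed = np.concatenate([
            np.zeros(20), swing_profile(1, gap_len=0), np.zeros(1)
        ])
        p = profile_from_speed(np.concatenate([speed, np.zeros(40)]))
        events = detect_events(p)
        strikes = heel_strikes(events, p)
        assert len(strikes) == 1
        majors = [e for e in events if e.kind == "major_peak"]
        valleys = [v for v in events if v.kind == "valley" and v.t_start > majors[0].t]
        expected = np.median(p.t[(p.t >= valleys[0].t_start) & (p.t <= valleys[0].t_end)])
        assert strikes[0].t == pytest.approx(expected, abs=1 / rate)

    def test_no_valley_no_strikes(self):
        p = profile_from_speed(np.full(60, 200.0))
        events = detect_events(p)
        assert heel_strikes(events, p) == []

    def test_one_strike_per_swing_even_with_fragmented_valley(self):
        speed = swing_profile(1, gap_len=30)
        # noise blip above the valley threshold splits the stance run but
        # must not yield a second strike
        speed[16 + 30 + 20] = 30.0
        p = profile_from_speed(np.concatenate([speed, np.zeros(20)]))
        events = detect_events(p)
        assert len(heel_strikes(events, p)) == 1


def strikes_at(xs, legs, times):
    return [
        GaitEvent("heel_strike", leg, t, position=(x, 0.0))
        for x, leg, t in zip(xs, legs, times)
    ]


class TestComputeParameters:
    def test_worked_example(self):
        strikes = strikes_at(
            [0.0, 0.6, 1.2, 1.8],
            ["left", "right", "left", "right"],
            [0.0, 0.5, 1.0, 1.5],
        )
        p = compute_parameters(strikes)
        assert p.step_length == pytest.approx(60.0)
        assert p.step_time == pytest.approx(0.5)
        assert p.stride_length == pytest.approx(120.0)
        assert p.stride_time == pytest.approx(1.0)
        assert p.cadence == pytest.approx(120.0)
        assert p.velocity == pytest.approx(120.0)
        assert p.n_steps == 4

    def test_too_few_strikes_error(self):
        strikes = strikes_at([0.0, 0.6], ["left", "right"], [0.0, 0.5])
        with pytest.raises(ValueError, match="too short"):
            compute_parameters(strikes)

    def test_consistency_invariants(self):
        strikes = strikes_at(
            np.arange(8) * 0.55,
            ["left", "right"] * 4,
            np.arange(8) * 0.48,
        )
        p = compute_parameters(strikes)
        assert p.cadence == pytest.approx(60.0 / p.step_time, rel=0.01)
        assert p.stride_time == pytest.approx(2 * p.step_time, rel=0.02)
        assert p.stride_length == pytest.approx(2 * p.step_length, rel=0.02)
        assert p.velocity == pytest.approx(
            p.step_length * p.cadence / 60.0, rel=0.03
        )

    def test_non_alternating_pairs_skipped(self):
        strikes = strikes_at(
            [0.0, 0.6, 1.0, 1.8],
            ["left", "right", "right", "left"],
            [0.0, 0.5, 0.9, 1.5],
        )
        p = compute_parameters(strikes)
        assert len(p.step_times) == 2  # the right->right pair is skipped
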