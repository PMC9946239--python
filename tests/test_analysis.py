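"""Trajectory measurement pipeline on constructed and simulated tracks."""

import math

import numpy as np
import pytest

from paramecium.analysis import (TrackedTrajectory, detect_avoiding_reactions,
                                 flip_correction, helicoid_fit, is_immobile,
                                 reorientation_angle,
                                 reorientation_before_after,
                                 select_trajectories, turning_balance,
                                 reaction_statistics)


def _swim_track(T=5.0, fps=50.0, speed=400.0, wobble=10.0, period=1.0,
                seed=0):
    """Forward swim with sinusoidal heading wobble (helicoid-like)."""
    t = np.arange(0.0, T, 1.0 / fps)
    gamma = wobble * np.sin(2 * math.pi * t / period)
    g = np.deg2rad(gamma)
    x = np.concatenate([[0.0], np.cumsum(speed * np.cos(g[:-1]) / fps)])
    y = np.concatenate([[0.0], np.cumsum(speed * np.sin(g[:-1]) / fps)])
    return TrackedTrajectory(t=t, x=x, y=y, gamma=gamma)


class TestFlipCorrection:
    def test_clean_trajectory_untouched(self):
        tr = _swim_track()
        out = flip_correction(tr)
        np.testing.assert_allclose(out.gamma, tr.gamma, atol=1e-9)

    def test_injected_180_flip_corrected(self):
        tr = _swim_track()
        bad = tr.gamma.copy()
        bad[100:140] += 180.0
        out = flip_correction(TrackedTrajectory(tr.t, tr.x, tr.y, bad))
        diff = (out.gamma - tr.gamma + 180.0) % 360.0 - 180.0
        assert np.max(np.abs(diff)) < 1e-9

    def test_smooth_subthreshold_turn_untouched(self):
        t = np.arange(0.0, 2.0, 0.02)
        gamma = 15.0 * 50.0 * 0.02 * np.arange(len(t)) * 0.0 + \
            np.cumsum(np.full(len(t), 15.0))       # 15 deg per frame
        gamma = (gamma + 180.0) % 360.0 - 180.0
        tr = TrackedTrajectory(t=t, x=np.cumsum(np.cos(np.deg2rad(gamma))),
                               y=np.cumsum(np.sin(np.deg2rad(gamma))),
                               gamma=gamma)
        out = flip_correction(tr)
        np.testing.assert_allclose(out.gamma, gamma, atol=1e-9)


class TestSelection:
    def test_short_track_rejected(self):
        tr = _swim_track(T=0.5)
        assert select_trajectories([tr]) == []

    def test_immobile_track_rejected(self):
        t = np.arange(0.0, 3.0, 0.02)
        tr = TrackedTrajectory(t=t, x=np.zeros_like(t) + 0.1 * t,
                               y=np.zeros_like(t), gamma=np.zeros_like(t))
        assert is_immobile(tr)
        assert select_trajectories([tr]) == []

    def test_helicoid_retained_circle_rejected(self):
        heli = _swim_track(T=6.0)
        assert abs(turning_balance(heli) - 0.5) < 0.05
        t = np.arange(0.0, 6.0, 0.02)
        gamma = (360.0 * t / 3.0 + 180.0) % 360.0 - 180.0   # circling
        g = np.deg2rad(gamma)
        circ = TrackedTrajectory(
            t=t, x=np.cumsum(300 * np.cos(g)) * 0.02,
            y=np.cumsum(300 * np.sin(g)) * 0.02, gamma=gamma)
        assert turning_balance(circ) in (0.0, 1.0)
        kept = select_trajectories([heli, circ])
        assert kept == [heli]


class TestAvoidingReactions:
    def test_straight_swim_has_none(self):
        assert detect_avoiding_reactions(_swim_track()) == []

    def test_constructed_backward_segment_detected(self):
        fps = 50.0
        t = np.arange(0.0, 4.0, 1.0 / fps)
        gamma = np.zeros_like(t)
        vx = np.full_like(t, 400.0)
        back = (t >= 2.0) & (t < 2.2)          # 200 ms backward
        vx[back] = -300.0
        x = np.concatenate([[0.0], np.cumsum(vx[:-1] / fps)])
        tr = TrackedTrajectory(t=t, x=x, y=np.zeros_like(t), gamma=gamma)
        rx = detect_avoiding_reactions(tr)
        assert len(rx) == 1
        assert rx[0].duration_ms == pytest.approx(200.0, abs=60.0)

    def test_single_pair_episode_discarded(self):
        fps = 50.0
        t = np.arange(0.0, 2.0, 1.0 / fps)
        vx = np.full_like(t, 400.0)
        vx[50:52] = -300.0                      # exactly one frame pair
        x = np.concatenate([[0.0], np.cumsum(vx[:-1] / fps)])
        tr = TrackedTrajectory(t=t, x=x, y=np.zeros_like(t),
                               gamma=np.zeros_like(t))
        assert detect_avoiding_reactions(tr) == []


class TestReorientation:
    def _reaction_track(self, turn_deg=90.0):
        fps = 50.0
        t = np.arange(0.0, 3.0, 1.0 / fps)
        gamma = np.zeros_like(t)
        back = (t >= 1.0) & (t < 1.3)
        turn_per_frame = turn_deg / back.sum()
        gamma[back] = np.cumsum(np.full(back.sum(), turn_per_frame))
        gamma[t >= 1.3] = turn_deg
        g = np.deg2rad(gamma)
        v = np.where(back, -200.0, 400.0)
        x = np.concatenate([[0.0], np.cumsum(v[:-1] * np.cos(g[:-1]) / fps)])
        y = np.concatenate([[0.0], np.cumsum(v[:-1] * np.sin(g[:-1]) / fps)])
        return TrackedTrajectory(t=t, x=x, y=y, gamma=gamma)

    def test_known_turn_angle_recovered(self):
        # detection clips one frame at each segment edge, so allow the
        # corresponding share of the injected turn (15 frames -> ~2/15)
        tr = self._reaction_track(90.0)
        rx = detect_avoiding_reactions(tr)
        assert len(rx) == 1
        ang = reorientation_angle(tr, rx[0])
        assert ang == pytest.approx(90.0, abs=15.0)

    def test_low_eccentricity_event_excluded(self):
        tr = self._reaction_track(90.0)
        ecc = np.ones_like(tr.t)
        ecc[(tr.t >= 1.05) & (tr.t < 1.1)] = 0.6
        tr2 = TrackedTrajectory(tr.t, tr.x, tr.y, tr.gamma, eccentricity=ecc)
        rx = detect_avoiding_reactions(tr2)
        assert reorientation_angle(tr2, rx[0]) is None

    def test_before_after_mode_recovers_step_turn(self):
        # instantaneous 60-degree heading step at t = 1 s
        fps = 50.0
        t = np.arange(0.0, 3.0, 1.0 / fps)
        gamma = np.where(t < 1.0, 0.0, 60.0)
        g = np.deg2rad(gamma)
        x = np.concatenate([[0.0], np.cumsum(400 * np.cos(g[:-1]) / fps)])
        y = np.concatenate([[0.0], np.cumsum(400 * np.sin(g[:-1]) / fps)])
        tr = TrackedTrajectory(t=t, x=x, y=y, gamma=gamma)
        ang = reorientation_before_after(tr, t_stim=1.0, window=1.0)
        assert ang == pytest.approx(60.0, abs=2.0)

    def test_no_turning_gives_zero(self):
        tr = _swim_track(wobble=0.0)
        ang = reorientation_before_after(tr, t_stim=2.0)
        assert ang == pytest.approx(0.0, abs=1e-9)


class TestHelicoidFit:
    def test_pure_sinusoid_exact_recovery(self):
        t = np.arange(0.0, 4.0, 0.02)
        gamma = 10.0 * np.sin(2 * math.pi * t / 0.8)
        tr = TrackedTrajectory(t=t, x=400 * t, y=np.zeros_like(t),
                               gamma=gamma)
        fit = helicoid_fit(tr)
        assert fit.ok
        # the linear-detrend step perturbs a finite sample slightly
        assert fit.period == pytest.approx(0.8, rel=1e-3)
        assert fit.amplitude == pytest.approx(10.0, rel=1e-3)

    def test_white_noise_flagged_low_confidence(self):
        rng = np.random.default_rng(5)
        t = np.arange(0.0, 4.0, 0.02)
        tr = TrackedTrajectory(t=t, x=400 * t, y=np.zeros_like(t),
                               gamma=rng.uniform(-30, 30, len(t)))
        assert not helicoid_fit(tr).ok

    def test_too_short_data_flagged(self):
        t = np.arange(0.0, 0.9, 0.02)
        tr = TrackedTrajectory(t=t, x=400 * t, y=np.zeros_like(t),
                               gamma=10 * np.sin(2 * math.pi * t / 0.8))
        assert not helicoid_fit(tr).ok


def test_reaction_statistics_pipeline():
    trs = []
    maker = TestReorientation()
    for turn in (40.0, 80.0, 120.0):
        trs.append(maker._reaction_track(turn))
    stats = reaction_statistics(trs)
    assert stats["n_reactions"] == 3
    assert stats["rate_hz"] == pytest.approx(3 / 9.0, rel=0.05)
    assert stats["mean_duration_ms"] > 0
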