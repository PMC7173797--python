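"""Kinematic extraction: resampling, smoothing, speed, onset detection,
movement segmentation, direction classification and IPD computation."""

import numpy as np
import pytest

from vraat.kinematics import (KinematicConfig, TrialTrajectory,
                              classify_direction, compute_ipd, compute_speed,
                              detect_onset, extract_movement, extract_trial,
                              resample_uniform, smooth_trajectory)
from vraat.synth import synthesize_step


def make_trajectory(t, x, z, direction="approach", experiment="AAT",
                    response_end=None, avatar_z=1.5, y=None):
    t = np.asarray(t, dtype=float)
    return TrialTrajectory(
        trial_id="T1", subject_id="S1", avatar_id="A1", experiment=experiment,
        orientation="gynophilic", avatar_sex="female", direction=direction,
        block=1, t=t, x=np.asarray(x, dtype=float),
        y=np.zeros_like(t) if y is None else np.asarray(y, dtype=float),
        z=np.asarray(z, dtype=float),
        stimulus_onset=float(t[0]),
        response_end=float(t[-1]) if response_end is None else response_end,
        avatar_x=0.0, avatar_z=avatar_z, start_distance=avatar_z)


class TestResample:
    def test_uniform_input_is_unchanged(self):
        t = np.arange(100) / 85.0
        x = np.sin(t)
        tu, pu = resample_uniform(t, np.column_stack([x, x, x]), 85.0)
        np.testing.assert_allclose(tu, t, atol=1e-12)
        np.testing.assert_allclose(pu[:, 0], x, atol=1e-12)

    def test_two_point_linear_interpolation(self):
        tu, pu = resample_uniform([0.0, 1.0], np.array([[0, 0, 0], [1, 0, 0]]), 4.0)
        np.testing.assert_allclose(pu[:, 0], [0, 0.25, 0.5, 0.75, 1.0])

    def test_jittered_linear_trajectory_preserved_exactly(self):
        rng = np.random.default_rng(0)
        t = np.sort(rng.uniform(0, 2, 60))
        t[0], t[-1] = 0.0, 2.0
        pos = np.column_stack([3 * t - 1, 0 * t, -0.5 * t + 2])
        tu, pu = resample_uniform(t, pos, 85.0)
        np.testing.assert_allclose(pu[:, 0], 3 * tu - 1, atol=1e-12)
        np.testing.assert_allclose(pu[:, 2], -0.5 * tu + 2, atol=1e-12)

    def test_duplicate_timestamps_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            resample_uniform([0.0, 0.0, 1.0], np.zeros((3, 3)), 10.0)


class TestSmoothing:
    def test_constant_series_unchanged(self):
        pos = np.full((40, 3), 2.5)
        np.testing.assert_allclose(smooth_trajectory(pos), pos, atol=1e-12)

    def test_quadratic_series_reproduced(self):
        t = np.arange(60, dtype=float)
        pos = np.column_stack([0.2 * t**2 - t + 3, t * 0, 0.01 * t**2])
        np.testing.assert_allclose(smooth_trajectory(pos), pos, atol=1e-9)

    def test_interior_matches_brute_force_polyfit(self):
        rng = np.random.default_rng(1)
        cfg = KinematicConfig()
        w, h = cfg.sg_window, cfg.sg_window // 2
        x = np.cumsum(rng.standard_normal(50)) * 0.01
        pos = np.column_stack([x, x * 0, x])
        sm = smooth_trajectory(pos, cfg)
        for i in range(h, len(x) - h):
            window = x[i - h:i + h + 1]
            coef = np.polyfit(np.arange(w), window, cfg.sg_order)
            assert sm[i, 0] == pytest.approx(np.polyval(coef, h), abs=1e-10)

    def test_too_short_series_error_names_required_length(self):
        with pytest.raises(ValueError, match="11"):
            smooth_trajectory(np.zeros((5, 3)))


class TestSpeed:
    def test_stationary_zero(self):
        t = np.arange(50) / 85.0
        assert np.all(compute_speed(t, np.ones((50, 3))) < 1e-9)

    def test_uniform_motion(self):
        t = np.arange(50) / 85.0
        pos = np.column_stack([t, 0 * t, 0 * t])  # 1 m/s along x
        np.testing.assert_allclose(compute_speed(t, pos), 1.0, atol=1e-9)

    def test_vertical_motion_ignored(self):
        t = np.arange(50) / 85.0
        pos = np.column_stack([0 * t, 5 * t, 0 * t])
        assert np.all(compute_speed(t, pos) == 0)

    def test_min_jerk_peak_closed_form(self):
        t = np.arange(0, 1.2, 1 / 85.0)
        z = synthesize_step(t, 0.0, 0.5, 0.1, 0.8)
        speed = compute_speed(t, np.column_stack([0 * t, 0 * t, z]))
        expected = 15 * 0.5 / (8 * 0.8)
        assert np.max(speed) == pytest.approx(expected, rel=0.02)


def onset_oracle(t, speed, stim, threshold, sustain):
    """Exhaustive linear scan for the first sustained crossing."""
    for i in range(len(t) - sustain + 1):
        if t[i] >= stim and all(speed[i + j] > threshold for j in range(sustain)):
            return t[i]
    return None


class TestOnset:
    def test_below_threshold_is_missing(self):
        t = np.arange(100) / 85.0
        assert detect_onset(t, np.full(100, 0.05), 0.0) is None

    def test_constructed_crossing_at_known_sample(self):
        t = np.arange(100) / 85.0
        speed = np.full(100, 0.02)
        speed[42:] = 0.5
        assert detect_onset(t, speed, 0.0) == t[42]

    def test_short_spike_rejected_by_sustain_rule(self):
        t = np.arange(100) / 85.0
        speed = np.full(100, 0.02)
        speed[10:12] = 0.5  # 2 samples < sustain_samples=3
        speed[50:] = 0.5
        assert detect_onset(t, speed, 0.0) == t[50]

    def test_matches_exhaustive_scan_oracle(self):
        rng = np.random.default_rng(2)
        cfg = KinematicConfig()
        t = np.arange(60) / 85.0
        for _ in range(300):
            speed = np.abs(rng.normal(0.08, 0.05, 60))
            stim = rng.choice([0.0, t[10]])
            got = detect_onset(t, speed, stim, cfg)
            want = onset_oracle(t, speed, stim, cfg.onset_threshold,
                                cfg.sustain_samples)
            assert got == want


class TestMovementExtraction:
    def _extract(self, traj, cfg=None):
        cfg = cfg or KinematicConfig()
        t, pos = traj.t, traj.positions
        speed = compute_speed(t, pos)
        onset = detect_onset(t, speed, traj.stimulus_onset, cfg)
        return t, pos, speed, onset

    def test_noise_free_step_recovered(self):
        t = np.arange(0, 2.0, 1 / 85.0)
        z = synthesize_step(t, 0.0, 0.5, 0.5, 0.8)
        traj = make_trajectory(t, 0 * t, z)
        tt, pos, speed, onset = self._extract(traj)
        peak, step, (s0, s1) = extract_movement(traj, tt, pos, speed, onset)
        assert peak == pytest.approx(15 * 0.5 / (8 * 0.8), rel=0.02)
        assert step == pytest.approx(50.0, abs=1.4)  # one sample at peak speed
        # segment ends where speed drops below the cutoff, shortly
        # before the nominal step end at 1.3 s
        assert s0 < 0.6 and 1.2 < s1 <= 1.3

    def test_interval_excludes_sub_cutoff_sway_tail(self):
        t = np.arange(0, 3.0, 1 / 85.0)
        z = synthesize_step(t, 0.0, 0.5, 0.2, 0.8)
        z = z + np.where(t > 1.2, 0.0005 * np.sin(40 * t), 0.0)  # slow sway
        traj = make_trajectory(t, 0 * t, z)
        tt, pos, speed, onset = self._extract(traj)
        _, _, (s0, s1) = extract_movement(traj, tt, pos, speed, onset)
        assert s1 < 1.3

    def test_two_separated_movements_first_segment_only(self):
        t = np.arange(0, 4.0, 1 / 85.0)
        z = (synthesize_step(t, 0.0, 0.3, 0.5, 0.6)
             + synthesize_step(t, 0.0, 0.6, 2.5, 0.5))  # faster second step
        traj = make_trajectory(t, 0 * t, z)
        tt, pos, speed, onset = self._extract(traj)
        peak, step, (s0, s1) = extract_movement(traj, tt, pos, speed, onset)
        # oracle: first supra-cutoff segment belongs to the first step only
        assert s1 < 2.5
        assert peak == pytest.approx(15 * 0.3 / (8 * 0.6), rel=0.05)
        assert step == pytest.approx(30.0, abs=1.5)

    def test_missing_onset_is_an_error(self):
        t = np.arange(0, 1.0, 1 / 85.0)
        traj = make_trajectory(t, 0 * t, 0 * t)
        with pytest.raises(ValueError, match="onset"):
            extract_movement(traj, t, traj.positions,
                             compute_speed(t, traj.positions), None)

    def test_rigid_rotation_invariance(self):
        t = np.arange(0, 2.0, 1 / 85.0)
        z = synthesize_step(t, 0.0, 0.5, 0.5, 0.8)
        x = 0 * t
        theta = 0.7
        c, s = np.cos(theta), np.sin(theta)
        traj0 = make_trajectory(t, x, z)
        xr, zr = c * x - s * z, s * x + c * z
        ax, az = -s * 1.5, c * 1.5  # avatar rotates with the frame
        traj1 = make_trajectory(t, xr, zr)
        traj1.avatar_x, traj1.avatar_z = ax, az
        r0, r1 = extract_trial(traj0), extract_trial(traj1)
        assert r1.peak_velocity == pytest.approx(r0.peak_velocity, abs=1e-9)
        assert r1.step_size == pytest.approx(r0.step_size, abs=1e-9)


class TestDirectionClassification:
    def _classify(self, traj):
        cfg = KinematicConfig()
        speed = compute_speed(traj.t, traj.positions)
        onset = detect_onset(traj.t, speed, traj.stimulus_onset, cfg)
        return classify_direction(traj, traj.t, traj.positions, onset, cfg)

    def test_monotone_forward_approach_is_correct(self):
        t = np.arange(0, 2.0, 1 / 85.0)
        z = synthesize_step(t, 0.0, 0.5, 0.5, 0.8)
        assert self._classify(make_trajectory(t, 0 * t, z)) == "correct"

    def test_opposite_excursion_beyond_limit_is_incorrect(self):
        t = np.arange(0, 2.0, 1 / 85.0)
        z = synthesize_step(t, 0.0, -0.12, 0.3, 0.5)  # 12 cm backward
        assert self._classify(make_trajectory(t, 0 * t, z,
                                              direction="approach")) == "incorrect"

    def test_no_movement_before_rating_is_missing(self):
        t = np.arange(0, 1.0, 1 / 85.0)
        assert self._classify(make_trajectory(t, 0 * t, 0 * t)) == "missing"

    def test_unknown_instruction_rejected(self):
        t = np.arange(0, 1.0, 1 / 85.0)
        traj = make_trajectory(t, 0 * t, 0 * t, direction="sideways")
        with pytest.raises(ValueError, match="instruction"):
            classify_direction(traj, t, traj.positions, 0.1)


class TestIPD:
    def test_head_at_avatar_position_is_zero(self):
        t = np.arange(0, 1.0, 1 / 85.0)
        traj = make_trajectory(t, 0 * t, np.full_like(t, 1.5), experiment="IPD")
        speed = compute_speed(t, traj.positions)
        ipd, _ = compute_ipd(traj, t, traj.positions, speed)
        assert ipd == pytest.approx(0.0, abs=1e-9)

    def test_three_four_five_triangle(self):
        t = np.arange(0, 1.0, 1 / 85.0)
        traj = make_trajectory(t, 0 * t, 0 * t, experiment="IPD")
        traj.avatar_x, traj.avatar_z = 0.3, 0.4
        speed = compute_speed(t, traj.positions)
        ipd, _ = compute_ipd(traj, t, traj.positions, speed)
        assert ipd == pytest.approx(50.0, abs=1e-9)

    def test_non_ipd_trial_rejected(self):
        t = np.arange(0, 1.0, 1 / 85.0)
        traj = make_trajectory(t, 0 * t, 0 * t, experiment="AAT")
        with pytest.raises(ValueError):
            compute_ipd(traj, t, traj.positions, compute_speed(t, traj.positions))


class TestTrajectoryValidation:
    def test_non_monotone_timestamps_rejected(self):
        t = np.array([0.0, 0.1, 0.05, 0.2])
        traj = make_trajectory(np.arange(4) * 0.01, np.zeros(4), np.zeros(4))
        traj.t = t
        with pytest.raises(ValueError, match="increasing"):
            traj.validate()

    def test_minimum_two_samples(self):
        traj = make_trajectory([0.0], [0.0], [0.0])
        with pytest.raises(ValueError, match="2 samples"):
            traj.validate()
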