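"""Feature pipeline: tracking, smoothing, cleaning, kinematics, angles,
template assembly."""

import numpy as np
import pytest
from dataclasses import replace

from gaitshield.features import (
    ANGLE_CHANNELS,
    DEFAULT_LAYOUT,
    KEYPOINT_NAMES,
    KeypointSequence,
    UnrecoverableChannelError,
    assemble_feature_vector,
    compute_angles,
    compute_kinematics,
    extract_features,
    kalman_smooth,
    remove_peaks_interpolate,
    track_subject,
)
from gaitshield.sigma_lognormal import SigmaLognormalParams, Stroke
from gaitshield.synthetic import HEALTHY_PROFILE, corrupt, generate_walker


def _line_sequence(n=10, step=(1.0, 2.0), dt=1.0):
    """All 14 keypoints translate rigidly along a line."""
    base = np.arange(14, dtype=float)[:, None] * [3.0, 5.0] + 10
    xy = np.array([base + np.array(step) * t for t in range(n)])
    return KeypointSequence.from_arrays(xy, dt=dt)


class TestTracking:
    def test_single_person_identity(self):
        seq = _line_sequence(6)
        frames = [seq.xy[t][None, :, :] for t in range(6)]
        tracked = track_subject(frames, seq.xy[0], dt=1.0)
        assert np.allclose(tracked.xy, seq.xy)

    def test_two_separated_walkers_follow_nearest_assignment_oracle(self):
        a = _line_sequence(8, step=(2.0, 0.0))
        b_xy = a.xy + np.array([500.0, 0.0])  # far parallel walker
        rng = np.random.default_rng(0)
        frames = []
        order = []
        for t in range(8):
            if rng.random() < 0.5:
                frames.append(np.stack([a.xy[t], b_xy[t]]))
                order.append((0, 1))
            else:
                frames.append(np.stack([b_xy[t], a.xy[t]]))
                order.append((1, 0))
        tracked = track_subject(frames, a.xy[0], dt=1.0)
        assert np.allclose(tracked.xy, a.xy)
        tracked_b = track_subject(frames, b_xy[0], dt=1.0)
        assert np.allclose(tracked_b.xy, b_xy)

    def test_empty_frame_marked_missing_then_resumes(self):
        seq = _line_sequence(6)
        frames = [seq.xy[t][None] if t != 3 else np.empty((0, 14, 2)) for t in range(6)]
        tracked = track_subject(frames, seq.xy[0], dt=1.0)
        assert tracked.missing[3].all()
        assert np.allclose(tracked.xy[4], seq.xy[4])

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            track_subject([], np.zeros((14, 2)))


class TestKalmanSmooth:
    def test_constant_velocity_track_passes_through(self):
        seq = _line_sequence(40, step=(1.5, -0.5), dt=1 / 30)
        out = kalman_smooth(seq)
        burn = 5
        err = np.abs(out.xy[burn:] - seq.xy[burn:])
        scale = np.abs(seq.xy[burn:]).mean()
        assert err.max() <= 0.01 * scale

    def test_noise_reduction_on_known_track_every_seed(self):
        prof = replace(HEALTHY_PROFILE, noise_px=0.0)
        gt = generate_walker(prof, 100, seed=1)
        for seed in range(20):
            rng = np.random.default_rng(seed)
            noisy = replace(gt, xy=gt.xy + rng.normal(0, 5, gt.xy.shape))
            sm = kalman_smooth(noisy)
            rmse_raw = np.sqrt(np.mean((noisy.xy - gt.xy) ** 2))
            rmse_sm = np.sqrt(np.mean((sm.xy - gt.xy) ** 2))
            assert rmse_sm < rmse_raw

    def test_gap_is_bridged_with_finite_predictions(self):
        seq = _line_sequence(12, dt=1 / 30)
        missing = seq.missing.copy()
        missing[5:8, :] = True
        xy = seq.xy.copy()
        xy[5:8] = np.nan
        gappy = replace(seq, xy=xy, missing=missing)
        out = kalman_smooth(gappy)
        assert np.isfinite(out.xy[5:8]).all()


class TestPeakRemoval:
    def test_missing_midpoint_linearly_interpolated(self):
        seq = _line_sequence(5, step=(1.0, 1.0), dt=1.0)
        xy = seq.xy.copy()
        missing = seq.missing.copy()
        xy[2, 0] = np.nan
        missing[2, 0] = True
        out = remove_peaks_interpolate(replace(seq, xy=xy, missing=missing))
        expected = (seq.xy[1, 0] + seq.xy[3, 0]) / 2
        assert np.allclose(out.xy[2, 0], expected)

    def test_spike_removed_and_refilled(self):
        seq = _line_sequence(30, step=(2.0, 0.0), dt=1.0)
        xy = seq.xy.copy()
        xy[15, 3] += 100 * 2.0  # 100x the median step on one keypoint
        spiked = replace(seq, xy=xy, missing=seq.missing.copy())
        out = remove_peaks_interpolate(spiked)
        assert np.abs(out.xy[15, 3] - seq.xy[15, 3]).max() <= 1.0

    def test_clean_input_is_identity(self):
        seq = _line_sequence(10, dt=1.0)
        out = remove_peaks_interpolate(seq)
        assert np.allclose(out.xy, seq.xy)

    def test_all_missing_channel_unrecoverable(self):
        seq = _line_sequence(5)
        missing = seq.missing.copy()
        missing[:, 2] = True
        xy = seq.xy.copy()
        xy[:, 2] = np.nan
        with pytest.raises(UnrecoverableChannelError):
            remove_peaks_interpolate(replace(seq, xy=xy, missing=missing))


class TestKinematics:
    def test_three_four_five_step(self):
        xy = np.zeros((2, 14, 2))
        xy[1] = [3.0, 4.0]
        seq = KeypointSequence.from_arrays(xy, dt=1.0)
        kin = compute_kinematics(seq).channels
        assert kin["d"][0] == pytest.approx(5.0)
        assert kin["v"][0] == pytest.approx(5.0)
        assert kin["a"][0] == pytest.approx(5.0)  # printed a = v / dt rule

    def test_difference_acceleration_mode(self):
        xy = np.zeros((3, 14, 2))
        xy[1] = [1.0, 0.0]
        xy[2] = [3.0, 0.0]
        seq = KeypointSequence.from_arrays(xy, dt=1.0)
        kin = compute_kinematics(seq, accel_mode="difference").channels
        assert kin["a"][0] == pytest.approx(1.0)  # (2 - 1) / 1

    def test_tangent_angle_is_quadrant_aware(self):
        xy = np.zeros((3, 14, 2))
        xy[1] = [1.0, 0.0]  # step +x
        xy[2] = [0.0, 0.0]  # step -x
        seq = KeypointSequence.from_arrays(xy, dt=1.0)
        rho = compute_kinematics(seq).channels["rho"]
        assert rho[0] == pytest.approx(0.0)
        assert abs(rho[1]) == pytest.approx(np.pi)

    def test_matches_brute_force_oracle_on_random_sequences(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            T = int(rng.integers(3, 8))
            dt = float(rng.uniform(0.01, 0.5))
            track = rng.normal(size=(T, 2)) * 10
            xy = np.tile(track[:, None, :], (1, 14, 1))
            seq = KeypointSequence.from_arrays(xy, dt=dt)
            kin = compute_kinematics(seq).channels
            for i in range(T - 1):
                dx = track[i + 1, 0] - track[i, 0]
                dy = track[i + 1, 1] - track[i, 1]
                d = np.sqrt(dx**2 + dy**2)
                assert kin["dx"][i] == pytest.approx(dx, abs=1e-12)
                assert kin["dy"][i] == pytest.approx(dy, abs=1e-12)
                assert kin["d"][i] == pytest.approx(d, abs=1e-12)
                assert kin["v"][i] == pytest.approx(d / dt, abs=1e-9)
                assert kin["vx"][i] == pytest.approx(dx / dt, abs=1e-9)
                assert kin["vy"][i] == pytest.approx(dy / dt, abs=1e-9)
                assert kin["a"][i] == pytest.approx(d / dt / dt, abs=1e-6)
                assert kin["rho"][i] == pytest.approx(np.arctan2(dy, dx), abs=1e-12)

    def test_too_few_frames_rejected(self):
        xy = np.zeros((1, 14, 2))
        with pytest.raises(ValueError):
            compute_kinematics(KeypointSequence.from_arrays(xy, dt=1.0))


class TestCornerAngles:
    def _coords(self, **overrides):
        coords = np.arange(28, dtype=float).reshape(14, 2)
        for name, val in overrides.items():
            coords[KEYPOINT_NAMES.index(name)] = val
        return coords

    def test_collinear_points_give_pi(self):
        coords = self._coords(
            shoulder_r=[0.0, 0.0], elbow_r=[1.0, 1.0], wrist_r=[2.0, 2.0]
        )
        assert compute_angles(coords)["angle_shoulder_elbow_wrist"] == pytest.approx(np.pi)

    def test_right_angle_configuration(self):
        coords = self._coords(
            hip_r=[0.0, 0.0], knee_r=[0.0, 1.0], ankle_r=[1.0, 1.0]
        )
        assert compute_angles(coords)["angle_hip_knee_ankle"] == pytest.approx(np.pi / 2)

    def test_degenerate_limb_is_nan(self):
        coords = self._coords(hip_r=[1.0, 1.0], knee_r=[1.0, 1.0], ankle_r=[2.0, 2.0])
        assert np.isnan(compute_angles(coords)["angle_hip_knee_ankle"])

    def test_matches_vector_math_oracle_on_random_triples(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            coords = rng.normal(size=(14, 2)) * 50
            angles = compute_angles(coords)
            hip_mid = (coords[8] + coords[11]) / 2
            u = coords[0] - coords[1]
            v = hip_mid - coords[1]
            expected = np.arccos(
                np.clip(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)), -1, 1)
            )
            assert angles["angle_nose_neck_hip"] == pytest.approx(expected, abs=1e-12)
            assert all(
                0 <= a <= np.pi for a in angles.values() if np.isfinite(a)
            )


class TestTemplateAssembly:
    def _slog(self):
        return SigmaLognormalParams(
            strokes=(Stroke(D=2.0, t0=0.1, mu=-1.0, sigma=0.3,
                            theta_start=0.1, theta_end=0.2),)
        )

    def test_default_layout_has_30_slots(self):
        seq = generate_walker(HEALTHY_PROFILE, 60, seed=2)
        _, _, vec = extract_features(seq)
        assert len(vec) == 30
        assert vec.layout == DEFAULT_LAYOUT

    def test_constant_channels_summarize_to_constant_and_zero_sd(self):
        import pandas as pd
        from gaitshield.features import GaitFeatureSequence

        table = pd.DataFrame({c: np.full(10, 3.5) for c in
                              ("d", "v", "vx", "vy", "a", "ay", "rho") + ANGLE_CHANNELS})
        kin = GaitFeatureSequence(channels=table, dt=1 / 30)
        vec = assemble_feature_vector(kin, self._slog())
        named = dict(zip(vec.layout, vec.values))
        assert named["v_mean"] == pytest.approx(3.5)
        assert named["v_sd"] == 0.0

    def test_permuting_layout_permutes_values(self):
        seq = generate_walker(HEALTHY_PROFILE, 60, seed=2)
        kin, slog, vec = extract_features(seq)
        perm = tuple(reversed(DEFAULT_LAYOUT))
        vec_p = assemble_feature_vector(kin, slog, layout_config=perm)
        assert np.allclose(vec_p.values, vec.values[::-1])

    def test_unknown_slot_rejected(self):
        seq = generate_walker(HEALTHY_PROFILE, 60, seed=2)
        kin, slog, _ = extract_features(seq)
        with pytest.raises(ValueError):
            assemble_feature_vector(kin, slog, layout_config=("no_such_channel",))


class TestPipelineProperties:
    def test_cleaning_stages_idempotent_on_clean_data(self):
        seq = generate_walker(HEALTHY_PROFILE, 80, seed=4)
        once = remove_peaks_interpolate(kalman_smooth(seq))
        twice = remove_peaks_interpolate(kalman_smooth(once))
        assert np.nanmean(np.linalg.norm(twice.xy - once.xy, axis=2)) <= 1.0

    def test_corrupt_clean_round_trip_error_bound(self):
        prof = replace(HEALTHY_PROFILE, noise_px=0.0)
        gt = generate_walker(prof, 120, seed=5)
        noisy = generate_walker(HEALTHY_PROFILE, 120, seed=5)
        bad = corrupt(noisy, missing_rate=0.05, spike_rate=0.02, spike_mag=20, seed=9)
        clean = remove_peaks_interpolate(kalman_smooth(bad))
        err = np.nanmean(np.linalg.norm(clean.xy - gt.xy, axis=2))
        assert err <= 2.0
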