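"""GM metric implementations against naive oracles and analytic limits."""

import numpy as np
import pytest

from gm3d.formats_io import POI_NAMES, read_metrics_report, write_metrics_report
from gm3d.gm_metrics import (
    MetricsConfig, compute_all_metrics, detect_bouts, differentiate,
    elbow_angle_series, metric_accel_xcorr, metric_dev_area,
    metric_outside_sd_area, metric_periodicity, metric_skewness,
    moving_stats, resample_uniform, _window_samples,
)
from gm3d.stream_sync import align_streams
from gm3d.depth_reconstruction import reconstruct_trajectories
from gm3d.synthetic_data import ScenarioSpec, generate_recording
from conftest import make_trajectory
from oracles import (autocorr_loop, bouts_loop, dev_area_loop,
                     moving_stats_loop, outside_sd_loop, pearson_loop,
                     skewness_loop)

RATE = 30.0
DT = 1.0 / RATE


class TestResampleAndDifferentiate:
    def test_uniform_input_unchanged_at_grid_points(self):
        n = 300
        rng = np.random.default_rng(31)
        pos = rng.normal(0, 50, (n, 6, 3)).cumsum(axis=0) / 10 + 900
        traj = make_trajectory(pos, rate_hz=RATE)
        ks = resample_uniform(traj, RATE)
        np.testing.assert_allclose(ks.position, pos, atol=1e-9)

    def test_cubic_polynomial_resampled_exactly_from_jittered_times(self):
        rng = np.random.default_rng(32)
        n = 200
        t_ms = np.arange(n) * 1000 / RATE + rng.uniform(-5, 5, n)
        t_ms.sort()
        t = t_ms / 1000
        pos = np.zeros((n, 6, 3))
        coefs = rng.uniform(-1, 1, (6, 3, 4))
        for p in range(6):
            for ax in range(3):
                pos[:, p, ax] = np.polyval(coefs[p, ax], t)
        traj = make_trajectory(pos)
        traj.slot_times_ms = t_ms
        ks = resample_uniform(traj, RATE)
        tg = (t_ms[0] + 1000 / RATE * np.arange(ks.n_samples)) / 1000
        for p in range(6):
            for ax in range(3):
                np.testing.assert_allclose(ks.position[:, p, ax],
                                           np.polyval(coefs[p, ax], tg),
                                           rtol=1e-9, atol=1e-9)

    def test_jittered_sine_within_a_tenth_percent(self):
        rng = np.random.default_rng(33)
        n = 300
        t_ms = np.arange(n) * 1000 / RATE + rng.uniform(-4, 4, n)
        t_ms.sort()
        A = 100.0
        pos = np.zeros((n, 6, 3))
        pos[:, :, 0] = A * np.sin(2 * np.pi * 1.0 * t_ms[:, None] / 1000)
        traj = make_trajectory(pos)
        traj.slot_times_ms = t_ms
        ks = resample_uniform(traj, RATE)
        tg = t_ms[0] / 1000 + ks.times_s
        err = np.abs(ks.position[:, 0, 0] - A * np.sin(2 * np.pi * tg))
        assert err.max() < 1e-3 * A

    def test_linear_ramp_velocity_and_zero_acceleration(self):
        n = 150
        pos = np.zeros((n, 6, 3))
        pos[:, :, :] = (np.arange(n) * 10 * DT)[:, None, None]
        ks = differentiate(resample_uniform(make_trajectory(pos), RATE))
        np.testing.assert_allclose(ks.velocity[1:-1], 10.0, rtol=1e-9)
        np.testing.assert_allclose(ks.acceleration[2:-2], 0.0, atol=1e-7)

    def test_sine_peak_speed_matches_analytic_derivative(self):
        n = 900
        A, f = 50.0, 1.0
        t = np.arange(n) * DT
        pos = np.zeros((n, 6, 3))
        pos[:, :, 0] = A * np.sin(2 * np.pi * f * t)[:, None]
        ks = differentiate(resample_uniform(make_trajectory(pos), RATE))
        assert ks.speed.max() == pytest.approx(A * 2 * np.pi * f, rel=0.01)

    def test_constant_position_has_zero_derivatives(self):
        pos = np.full((200, 6, 3), 900.0)
        ks = differentiate(resample_uniform(make_trajectory(pos), RATE))
        assert np.all(ks.speed == 0) and np.all(ks.accel_mag == 0)


class TestMovingStats:
    def test_constant_series(self):
        ma, sd = moving_stats(np.full(200, 7.0), 2.0, RATE)
        np.testing.assert_array_equal(ma, 7.0)
        np.testing.assert_array_equal(sd, 0.0)

    def test_linear_ramp_interior_equals_ramp(self):
        x = np.arange(300, dtype=float)
        ma, _ = moving_stats(x, 2.0, RATE)
        half = _window_samples(2.0, RATE) // 2
        np.testing.assert_allclose(ma[half:-half], x[half:-half], rtol=1e-12)

    def test_matches_per_window_loop_oracle(self):
        rng = np.random.default_rng(34)
        x = rng.normal(0, 1, 400)
        ma, sd = moving_stats(x, 2.0, RATE)
        half = _window_samples(2.0, RATE) // 2
        ma_o, sd_o = moving_stats_loop(x, half)
        np.testing.assert_allclose(ma, ma_o, atol=1e-9)
        np.testing.assert_allclose(sd, sd_o, atol=1e-9)
        # white noise: interior moving SD near 1 on average
        assert abs(sd[half:-half].mean() - 1.0) < 0.1


class TestAreaMetrics:
    def test_series_equal_to_its_average_gives_zero(self):
        assert metric_dev_area(np.full(300, 5.0), 2.0, RATE) == 0.0

    def test_sine_area_matches_quadrature(self):
        # MA of whole periods vanishes, |sin| integrates to 2/pi per period
        n = 301  # 10 s
        t = np.arange(n) * DT
        x = np.sin(2 * np.pi * 1.0 * t)
        got = metric_dev_area(x, 2.0, RATE)
        ma, _ = moving_stats(x, 2.0, RATE)
        oracle = dev_area_loop(x, ma, DT, 2.0)
        assert got == pytest.approx(oracle, abs=1e-12)
        assert got == pytest.approx(10.0 * (2 / np.pi) / 2.0, rel=0.05)

    def test_amplitude_homogeneity(self):
        rng = np.random.default_rng(35)
        x = rng.normal(0, 1, 300)
        assert metric_dev_area(2 * x, 2.0, RATE) == pytest.approx(
            2 * metric_dev_area(x, 2.0, RATE), rel=1e-12)

    def test_outside_sd_zero_for_constant_and_tiny_for_square_wave(self):
        assert metric_outside_sd_area(np.full(300, 3.0), 2.0, RATE) == 0.0
        t = np.arange(600) * DT
        square = np.where(np.sin(2 * np.pi * 2.5 * (t + DT / 2)) >= 0, 1.0, -1.0)
        # MA ~ 0 and sample SD slightly above the amplitude: near-zero
        # exceedance (the odd window cannot balance +-A exactly)
        got = metric_outside_sd_area(square, 2.0, RATE)
        ma, sd = moving_stats(square, 2.0, RATE)
        assert got == pytest.approx(outside_sd_loop(square, ma, sd, DT, 2.0,
                                                    "window"), abs=1e-12)
        assert got < 0.02 * metric_dev_area(square, 2.0, RATE)

    def test_spikes_give_mean_exceedance_matching_loop(self):
        rng = np.random.default_rng(36)
        x = rng.normal(0, 1, 600)
        x[[50, 150, 300, 450, 550]] += 30.0
        ma, sd = moving_stats(x, 2.0, RATE)
        for norm in ("outside_samples", "window"):
            got = metric_outside_sd_area(x, 2.0, RATE, norm)
            oracle = outside_sd_loop(x, ma, sd, DT, 2.0, norm)
            assert got == pytest.approx(oracle, abs=1e-9)


class TestPeriodicityAndSkewness:
    def test_pure_sinusoid_near_one(self):
        t = np.arange(1800) * DT
        assert metric_periodicity(np.sin(2 * np.pi * 1.0 * t), RATE) >= 0.95

    def test_white_noise_low(self):
        vals = [metric_periodicity(np.random.default_rng(s).normal(0, 1, 1800),
                                   RATE) for s in range(20)]
        assert max(vals) < 0.2

    def test_matches_naive_autocorrelation_oracle(self):
        rng = np.random.default_rng(37)
        t = np.arange(300) * DT
        x = np.sin(2 * np.pi * 1.3 * t) + rng.normal(0, 1, 300)
        x = x - x.mean()
        got = metric_periodicity(x, RATE, 0.25)
        oracle = autocorr_loop(x, max(int(round(0.25 * RATE)), 1), 150)
        assert got == pytest.approx(oracle, abs=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            metric_periodicity(np.zeros(600), RATE)

    def test_mirrored_sample_has_zero_skewness(self):
        rng = np.random.default_rng(38)
        half = rng.normal(3, 2, 500)
        v = np.concatenate([half, 2 * half.mean() - half])  # symmetric about mean
        assert metric_skewness(v) == pytest.approx(0.0, abs=1e-10)

    def test_exponential_sample_skewness_near_two(self):
        v = np.random.default_rng(39).exponential(1.0, 100_000)
        assert metric_skewness(v) == pytest.approx(2.0, abs=0.05)
        assert metric_skewness(v) == pytest.approx(skewness_loop(v), abs=1e-9)

    def test_skewness_scale_invariant(self):
        v = np.random.default_rng(40).gamma(2, 1, 1000)
        assert metric_skewness(5 * v) == pytest.approx(metric_skewness(v), rel=1e-12)


class TestBilateralXcorr:
    def test_identical_and_mirrored_signals(self):
        rng = np.random.default_rng(41)
        a = rng.normal(0, 1, 500)
        assert metric_accel_xcorr(a, a) == pytest.approx(1.0)
        assert metric_accel_xcorr(a, 2 * a.mean() - a) == pytest.approx(-1.0)

    def test_ar1_innovation_correlation_recovered(self):
        rng = np.random.default_rng(42)
        n, rho, a = 10_000, 0.5, 0.7
        cov = [[1, rho], [rho, 1]]
        e = rng.multivariate_normal([0, 0], cov, n)
        x = np.zeros((n, 2))
        for i in range(1, n):
            x[i] = a * x[i - 1] + e[i]
        got = metric_accel_xcorr(x[:, 0], x[:, 1])
        assert got == pytest.approx(0.5, abs=0.05)
        assert got == pytest.approx(pearson_loop(x[:, 0], x[:, 1]), abs=1e-9)

    def test_max_lag_mode_finds_shifted_copy(self):
        rng = np.random.default_rng(43)
        a = rng.normal(0, 1, 600)
        b = np.roll(a, 5)
        assert metric_accel_xcorr(a, b, mode="zero_lag") < 0.5
        assert metric_accel_xcorr(a, b, mode="max_lag") > 0.9


class TestElbowAngle:
    def test_collinear_and_right_angle(self):
        s = np.array([[0.0, 0, 900]])
        e = np.array([[100.0, 0, 900]])
        w = np.array([[200.0, 0, 900]])
        angles, _ = elbow_angle_series(s, e, w)
        assert angles[0] == pytest.approx(180.0)
        w_perp = np.array([[100.0, 80, 900]])
        angles, _ = elbow_angle_series(s, e, w_perp)
        assert angles[0] == pytest.approx(90.0)

    def test_degenerate_segment_skipped_and_counted(self):
        s = np.array([[0.0, 0, 900], [0, 0, 900]])
        e = np.array([[100.0, 0, 900], [0, 0, 905]])  # 5 mm segment
        w = np.array([[200.0, 0, 900], [80, 0, 900]])
        angles, skipped = elbow_angle_series(s, e, w)
        assert skipped == 1 and np.isnan(angles[1])

    def test_synthetic_flexion_rom(self):
        # elbow angle oscillating 60..140 degrees by construction
        n = 600
        t = np.arange(n) * DT
        theta = np.radians(100 + 40 * np.sin(2 * np.pi * 0.5 * t))
        s = np.tile([0.0, -90.0, 900.0], (n, 1))
        e = np.tile([0.0, 0.0, 900.0], (n, 1))
        w = np.column_stack([80 * np.sin(theta), -80 * np.cos(theta),
                             np.full(n, 900.0)])
        angles, _ = elbow_angle_series(s, e, w)
        rom = angles.max() - angles.min()
        assert rom == pytest.approx(80.0, abs=0.5)


class TestBouts:
    def test_all_zero_speed(self):
        b = detect_bouts(np.zeros(900), RATE)
        assert b.n_bouts == 0 and b.movement_pct == 0.0

    def test_constant_positive_speed_single_full_bout(self):
        b = detect_bouts(np.full(900, 50.0), RATE)
        assert b.n_bouts == 1
        assert b.movement_pct == 100.0
        assert b.intervals[0] == (0.0, 900 * DT)

    def test_three_episode_profile_exact_bookkeeping(self):
        n = 1800  # 60 s
        speed = np.ones(n)  # sub-threshold background
        episodes = [(300, 360), (700, 790), (1200, 1350)]  # 2 s, 3 s, 5 s
        for a, b in episodes:
            speed[a:b] = 100.0
        bouts = detect_bouts(speed, RATE, 0.05)
        assert bouts.n_bouts == 3
        assert bouts.mean_duration_s == pytest.approx(10 / 3, abs=1e-12)
        assert bouts.movement_pct == pytest.approx(100 * 300 / 1800, abs=1e-12)
        intervals, durations, pct = bouts_loop(speed, DT, 0.05)
        assert bouts.intervals == intervals
        assert pct == bouts.movement_pct


class TestComputeAll:
    @staticmethod
    def chain(spec, config=None):
        rec = generate_recording(spec)
        al = align_streams(rec.rgb_ts, rec.depth_ts)
        traj = reconstruct_trajectories(rec.track, rec.depth, al, rec.spec.camera)
        return rec, compute_all_metrics(traj, config)

    def test_stationary_scenario_all_quiet(self):
        spec = ScenarioSpec(seed=51, duration_s=10.0,
                            timestamp_jitter_ms_sd=0.0, depth_clock_offset_ms=0.0,
                            drop_rate_rgb=0.0, drop_rate_depth=0.0,
                            wrist_amp_mm=(0, 0, 0), elbow_amp_mm=(0, 0, 0),
                            shoulder_amp_mm=(0, 0, 0), tremor_sd_mm=0.0,
                            black_area_rate=0.0, low_confidence_rate=0.0,
                            misalignment_spikes_per_poi=0)
        _, ms = self.chain(spec)
        for side in ("left", "right"):
            assert ms.bouts[side].n_bouts == 0
            assert ms.bouts[side].movement_pct == 0.0
            assert ms.metrics[side]["traj_dev_area"] == pytest.approx(0.0, abs=1e-9)
            assert ms.metrics[side]["speed_dev_area"] == pytest.approx(0.0, abs=1e-9)
            assert ms.metrics[side]["traj_periodicity"] is None  # zero variance
            assert ms.metrics[side]["speed_skewness"] is None
        assert ms.metrics["combined"]["accel_xcorr"] is None

    def test_mirror_symmetric_arms(self):
        spec = ScenarioSpec(seed=52, duration_s=20.0, bilateral_coupling=1.0,
                            timestamp_jitter_ms_sd=0.0, depth_clock_offset_ms=0.0,
                            drop_rate_rgb=0.0, drop_rate_depth=0.0,
                            black_area_rate=0.0, low_confidence_rate=0.0,
                            misalignment_spikes_per_poi=0)
        _, ms = self.chain(spec)
        assert ms.metrics["combined"]["accel_xcorr"] == pytest.approx(1.0, abs=0.01)
        for key in ("traj_dev_area", "speed_dev_area", "speed_skewness",
                    "elbow_rom_deg"):
            left = ms.metrics["left"][key]
            right = ms.metrics["right"][key]
            assert left == pytest.approx(right, rel=0.01), key

    def test_repeat_runs_bit_identical_reports(self, tmp_path):
        spec = ScenarioSpec(seed=53, duration_s=10.0)
        _, ms1 = self.chain(spec)
        _, ms2 = self.chain(spec)
        p1 = write_metrics_report(ms1, tmp_path / "a")[0]
        p2 = write_metrics_report(ms2, tmp_path / "b")[0]
        assert p1.read_bytes() == p2.read_bytes()

    def test_report_round_trip_preserves_values(self, tmp_path):
        _, ms = self.chain(ScenarioSpec(seed=54, duration_s=10.0))
        jp, cp = write_metrics_report(ms, tmp_path / "m")
        back = read_metrics_report(jp)
        assert back.metrics == ms.metrics
        assert back.bouts["left"].intervals == ms.bouts["left"].intervals
        # flat CSV exposes exactly nine metric keys per side grouping
        header = cp.read_text().splitlines()[0].split(",")
        for side in ("left", "right", "combined"):
            assert sum(h.endswith(f"_{side}") and not h.startswith("bout_")
                       for h in header) == 9

    def test_translation_invariance_and_scale_homogeneity(self):
        rec = generate_recording(ScenarioSpec(seed=55, duration_s=12.0,
                                              **dict(timestamp_jitter_ms_sd=0.0,
                                                     depth_clock_offset_ms=0.0,
                                                     drop_rate_rgb=0.0,
                                                     drop_rate_depth=0.0,
                                                     black_area_rate=0.0,
                                                     low_confidence_rate=0.0,
                                                     misalignment_spikes_per_poi=0)))
        al = align_streams(rec.rgb_ts, rec.depth_ts)
        traj = reconstruct_trajectories(rec.track, rec.depth, al, rec.spec.camera)
        base = compute_all_metrics(traj)

        shifted = make_trajectory(traj.xyz + np.array([100.0, -50.0, 30.0]))
        shifted.slot_times_ms = traj.slot_times_ms
        ms_shift = compute_all_metrics(shifted)
        scaled = make_trajectory(traj.xyz * 2.0)
        scaled.slot_times_ms = traj.slot_times_ms
        ms_scale = compute_all_metrics(scaled)

        for side in ("left", "right"):
            for key in ("traj_dev_area", "traj_outside_sd_area",
                        "speed_dev_area", "speed_outside_sd_area"):
                assert ms_shift.metrics[side][key] == pytest.approx(
                    base.metrics[side][key], rel=1e-9)
                assert ms_scale.metrics[side][key] == pytest.approx(
                    2 * base.metrics[side][key], rel=1e-6), key
            for key in ("traj_periodicity", "speed_periodicity",
                        "speed_skewness", "elbow_rom_deg"):
                assert ms_scale.metrics[side][key] == pytest.approx(
                    base.metrics[side][key], rel=1e-6), key
            assert ms_scale.bouts[side].n_bouts == base.bouts[side].n_bouts
            assert ms_scale.bouts[side].movement_pct == pytest.approx(
                base.bouts[side].movement_pct)
        assert ms_scale.metrics["combined"]["accel_xcorr"] == pytest.approx(
            base.metrics["combined"]["accel_xcorr"], rel=1e-6)
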