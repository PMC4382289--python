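"""Stride extraction, band coverage, TK onset detection, metabolic
summaries, and the synthetic fixture generator."""

import numpy as np
import pytest

from reflexgait.gait_analysis import (CYCLE_GRID, GaitCycleCurve,
                                      ReferenceBand, band_coverage,
                                      bands_from_csv, bands_to_csv,
                                      generate_fixtures, mean_stride_curves,
                                      metabolic_summary,
                                      teager_kaiser_energy,
                                      teager_kaiser_onsets)
from tests.conftest import make_trajectory


class TestBandCoverage:
    def test_curve_on_mean_is_full_coverage(self):
        fx = generate_fixtures(1)
        band = fx.bands["hip_angle"]
        curve = GaitCycleCurve("hip_angle", band.mean.copy())
        assert band_coverage(curve, band) == 100.0

    def test_half_outside_is_fifty_percent(self):
        mean = np.zeros(101)
        sd = np.ones(101)
        band = ReferenceBand("x", mean, sd)
        values = np.zeros(101)
        values[:50] = 5.0            # 50 of 101 points outside
        curve = GaitCycleCurve("x", values)
        assert band_coverage(curve, band) == pytest.approx(100 * 51 / 101)

    def test_boundary_counts_as_inside(self):
        band = ReferenceBand("x", np.zeros(101), np.zeros(101))
        curve = GaitCycleCurve("x", np.zeros(101))
        assert band_coverage(curve, band) == 100.0

    def test_monotone_as_sd_shrinks(self):
        rng = np.random.default_rng(0)
        mean = np.zeros(101)
        values = rng.normal(0, 1.0, 101)
        curve = GaitCycleCurve("x", values)
        cov = [band_coverage(curve, ReferenceBand("x", mean,
                                                  np.full(101, s)))
               for s in (2.0, 1.0, 0.5, 0.25)]
        assert all(b >= a for a, b in zip(cov[1:], cov[:-1]))
        assert all(0.0 <= c <= 100.0 for c in cov)

    def test_grid_mismatch_raises(self):
        band = ReferenceBand("x", np.zeros(101), np.ones(101))
        with pytest.raises(ValueError):
            GaitCycleCurve("x", np.zeros(50))
        with pytest.raises(ValueError):
            ReferenceBand("x", np.zeros(101), -np.ones(101))


class TestMeanStride:
    def test_identical_strides_average_to_single_stride(self):
        fx = generate_fixtures(2)
        ms = mean_stride_curves(fx.trajectory_t, fx.trajectory_channels,
                                fx.heel_strikes, com_x=fx.com_x)
        # channels are exactly periodic: the mean equals one stride
        T = fx.stride_time
        ts = (CYCLE_GRID / 100.0) * T + 2 * T
        expect = np.interp(ts, fx.trajectory_t,
                           fx.trajectory_channels["hip_angle"])
        assert np.allclose(ms.curves["hip_angle"].values, expect, atol=1e-6)
        assert ms.stride_time == pytest.approx(T)
        assert ms.stride_length == pytest.approx(1.4 * T, rel=1e-6)

    def test_first_two_strides_are_ignored(self):
        fx = generate_fixtures(3)
        y = fx.trajectory_channels["hip_angle"].copy()
        # corrupt only the first two strides
        y[fx.trajectory_t < 2 * fx.stride_time] += 99.0
        ms_ref = mean_stride_curves(fx.trajectory_t,
                                    {"hip_angle": fx.trajectory_channels[
                                        "hip_angle"]},
                                    fx.heel_strikes)
        ms = mean_stride_curves(fx.trajectory_t, {"hip_angle": y},
                                fx.heel_strikes)
        assert np.allclose(ms.curves["hip_angle"].values[1:-1],
                           ms_ref.curves["hip_angle"].values[1:-1],
                           atol=1e-9)

    def test_alternating_durations_mean_stride_time(self):
        T = 1.0
        hs = np.array([0.0, T, 2 * T, 3.2 * T, 4.2 * T, 5.4 * T])
        t = np.arange(0.0, 6.0, 0.01)
        ms = mean_stride_curves(t, {"x": np.sin(t)}, hs)
        included = [1.2 * T, 1.0 * T, 1.2 * T]
        assert ms.stride_time == pytest.approx(np.mean(included))
        assert ms.n_strides == 3

    def test_too_few_strides_error_names_count(self):
        t = np.arange(0.0, 2.0, 0.01)
        with pytest.raises(ValueError, match="got 2"):
            mean_stride_curves(t, {"x": np.sin(t)}, np.array([0.0, 0.5, 1.0]))

    def test_idempotent_on_periodic_trajectory(self):
        fx = generate_fixtures(4)
        ms1 = mean_stride_curves(fx.trajectory_t, fx.trajectory_channels,
                                 fx.heel_strikes)
        # re-averaging the averaged curve (as a periodic signal) is a no-op
        T = fx.stride_time
        t2 = np.arange(0.0, 6 * T, 0.01)
        periodic = {
            "hip_angle": np.interp(np.mod(t2, T) / T * 100.0, CYCLE_GRID,
                                   ms1.curves["hip_angle"].values)}
        hs2 = np.arange(7) * T
        ms2 = mean_stride_curves(t2, periodic, hs2[hs2 <= t2[-1] + 1e-9])
        assert np.allclose(ms2.curves["hip_angle"].values,
                           ms1.curves["hip_angle"].values, atol=5e-3)


class TestTeagerKaiser:
    def test_constant_signal_has_zero_energy_and_no_onsets(self):
        x = np.full(3000, 0.7)
        assert np.allclose(teager_kaiser_energy(x), 0.0)
        assert teager_kaiser_onsets(x, 1500.0) == []

    def test_short_signal_raises(self):
        with pytest.raises(ValueError):
            teager_kaiser_energy(np.array([1.0, 2.0]))

    def test_pure_baseline_noise_yields_no_intervals(self):
        rng = np.random.default_rng(12)
        for _ in range(5):
            x = rng.normal(0, 0.01, 4500)
            assert teager_kaiser_onsets(x, 1500.0, n_sd=6.0) == []

    def test_burst_recovered_at_known_times(self):
        fx = generate_fixtures(5)
        intervals = teager_kaiser_onsets(fx.emg, fx.emg_fs, n_sd=6.0)
        assert len(intervals) >= len(fx.emg_bursts) - 1
        for (on, off) in fx.emg_bursts[1:-1]:
            overlaps = [iv for iv in intervals
                        if iv[1] > on and iv[0] < off]
            assert overlaps, f"burst ({on}, {off}) not detected"
            # detected interval lands near the true burst
            d_on = min(abs(iv[0] - on) for iv in overlaps)
            assert d_on < 0.1


class TestMetabolicSummary:
    def test_constant_power_division(self):
        traj = make_trajectory(metabolic=320.0, body_mass=80.0,
                               heel_strikes_r=np.arange(8) * 1.1)
        out = metabolic_summary(traj)
        assert out["net_w_per_kg"] == pytest.approx(4.0)

    def test_percent_change_vs_reference(self):
        traj = make_trajectory(metabolic=400.0, body_mass=80.0)
        out = metabolic_summary(traj, reference_w_per_kg=4.0)
        assert out["percent_change"] == pytest.approx(25.0)

    def test_loaded_trial_divides_by_unloaded_mass(self):
        traj = make_trajectory(metabolic=320.0, body_mass=80.0,
                               back_mass=32.0)
        out = metabolic_summary(traj)
        assert out["net_w_per_kg"] == pytest.approx(320.0 / 80.0)


class TestFixtures:
    def test_deterministic_for_fixed_seed(self):
        a, b = generate_fixtures(9), generate_fixtures(9)
        assert np.array_equal(a.emg, b.emg)
        assert np.array_equal(a.bands["hip_angle"].sd,
                              b.bands["hip_angle"].sd)
        c = generate_fixtures(10)
        assert not np.array_equal(a.emg, c.emg)

    def test_bands_csv_round_trip(self, tmp_path):
        fx = generate_fixtures(6)
        path = tmp_path / "bands.csv"
        bands_to_csv(fx.bands, path)
        back = bands_from_csv(path)
        for name, band in fx.bands.items():
            assert np.allclose(back[name].mean, band.mean)
            assert np.allclose(back[name].sd, band.sd)
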