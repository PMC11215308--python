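"""Tests of the synthetic generators: determinism, wave kinematics,
band-limited vasomotion, epoch statistics, and the degenerate cases."""

import numpy as np
import pytest
from scipy.signal import welch

from neurovasc import synthetic_data as sd


def small_config(**kw):
    defaults = dict(seed=0, duration_s=120.0, grid_shape=(8, 6), pixel_size_mm=0.1,
                    vasomotion_sd=0.0, noise_sd=0.0)
    defaults.update(kw)
    return sd.SimConfig(**defaults)


class TestFlowMovieGenerator:
    def test_degenerate_config_gives_constant_frames(self):
        movie = sd.gen_flow_movie(small_config(baseline_flow=73.0))
        assert movie.frames.shape == (240, 8, 6)
        assert np.all(movie.frames == 73.0)

    def test_frame_count_matches_duration(self):
        movie = sd.gen_flow_movie(small_config(duration_s=90.0, frame_rate_hz=2.0))
        assert movie.n_frames == 180
        assert movie.duration_s == 90.0

    def test_wave_peak_delay_between_two_pixels(self):
        # planar wave at 9.1 mm/min; probe pixels 3.0 mm apart along the
        # propagation axis should peak ~19.78 s apart (3.0 / (9.1/60) s)
        wave = sd.CSDWaveSpec(origin_xy_mm=(0.0, 1.0), onset_s=60.0,
                              velocity_mm_per_min=9.1, kind="planar")
        cfg = sd.SimConfig(seed=0, duration_s=300.0, grid_shape=(40, 80),
                           pixel_size_mm=0.05, vasomotion_sd=0.0, noise_sd=0.0,
                           csd_events=[wave])
        movie = sd.gen_flow_movie(cfg)
        t1 = np.argmax(movie.frames[:, 20, 10]) / 2.0  # x = 0.525 mm
        t2 = np.argmax(movie.frames[:, 20, 70]) / 2.0  # x = 3.525 mm
        assert abs((t2 - t1) - 19.78) <= 0.5  # one frame interval

    def test_radial_arrival_time_is_affine_in_distance(self):
        wave = sd.CSDWaveSpec(origin_xy_mm=(0.3, 0.3), onset_s=30.0,
                              velocity_mm_per_min=6.0)
        cfg = sd.SimConfig(seed=0, duration_s=150.0, grid_shape=(20, 40),
                           pixel_size_mm=0.1, vasomotion_sd=0.0, noise_sd=0.0,
                           csd_events=[wave])
        movie = sd.gen_flow_movie(cfg)
        rows, cols = cfg.grid_shape
        x = (np.arange(cols)[None, :] + 0.5) * 0.1
        y = (np.arange(rows)[:, None] + 0.5) * 0.1
        dist = np.sqrt((x - 0.3) ** 2 + (y - 0.3) ** 2).ravel()
        peak_t = movie.frames.reshape(movie.n_frames, -1).argmax(axis=0) / 2.0
        slope, intercept = np.polyfit(dist, peak_t, 1)
        pred = slope * dist + intercept
        r2 = 1 - np.sum((peak_t - pred) ** 2) / np.sum((peak_t - peak_t.mean()) ** 2)
        assert r2 > 0.999
        assert slope == pytest.approx(60.0 / 6.0, rel=0.02)  # 1/velocity in s/mm

    def test_vasomotion_power_concentrated_in_band(self):
        cfg = sd.SimConfig(seed=1, duration_s=2400.0, grid_shape=(3, 3),
                           vasomotion_sd=0.05, noise_sd=0.0)
        movie = sd.gen_flow_movie(cfg)
        f, p = welch(movie.frames[:, 0, 0], fs=2.0, nperseg=512, detrend="constant")
        band = (f >= 0.05) & (f <= 0.15)
        assert p[band].sum() / p[1:].sum() > 0.8

    def test_seed_determinism_golden(self):
        cfg = dict(seed=12345, duration_s=120.0, grid_shape=(8, 6), pixel_size_mm=0.1,
                   csd_events=[sd.CSDWaveSpec(origin_xy_mm=(0.2, 0.2), onset_s=30.0,
                                              velocity_mm_per_min=6.0)])
        a = sd.gen_flow_movie(sd.SimConfig(**cfg))
        b = sd.gen_flow_movie(sd.SimConfig(**cfg))
        assert np.array_equal(a.frames, b.frames)
        # frozen fingerprint of the seeded generator output
        assert a.frames[100, 3, 2] == pytest.approx(101.57136608158707, abs=1e-9)
        assert a.frames.sum() == pytest.approx(1243444.5407258074, rel=1e-12)

    @pytest.mark.parametrize("bad_band", [(0.0, 0.15), (0.15, 0.05), (0.05, 1.5)])
    def test_band_outside_nyquist_rejected(self, bad_band):
        with pytest.raises(ValueError):
            small_config(vasomotion_band_hz=bad_band)

    def test_invalid_wave_specs_rejected(self):
        with pytest.raises(ValueError):
            sd.CSDWaveSpec(velocity_mm_per_min=0.0)
        with pytest.raises(ValueError):
            sd.CSDWaveSpec(velocity_mm_per_min=-3.0)
        with pytest.raises(ValueError):
            small_config(csd_events=[sd.CSDWaveSpec(onset_s=500.0)])  # beyond 120 s

    def test_non_integer_frame_count_rejected(self):
        with pytest.raises(ValueError):
            small_config(duration_s=100.3)


class TestCSDTrace:
    def test_noiseless_trace_baseline_is_one(self):
        tr = sd.gen_csd_trace([600.0], noise_sd=0.0)
        assert tr.rcbf_n[:120].mean() == pytest.approx(1.0, abs=1e-6)
        assert tr.rcbf_n.max() == pytest.approx(1.4, abs=0.01)  # +40% hyperemia

    def test_non_recovering_trace_ends_below_baseline(self):
        tr = sd.gen_csd_trace([600.0], noise_sd=0.0, recovers=[False])
        assert np.median(tr.rcbf_n[-120:]) < 0.9


class TestSSEPGenerator:
    def test_zero_noise_epochs_equal_template(self):
        cfg = sd.SSEPSimConfig(noise_sd_uV=0.0)
        epochs = sd.gen_ssep_epochs(cfg)
        tpl = sd.ssep_template(cfg)
        assert epochs.n_epochs == 90
        assert np.array_equal(epochs.epochs, np.tile(tpl, (90, 1)))

    def test_single_epoch_average_is_identity(self):
        cfg = sd.SSEPSimConfig(n_epochs=1, noise_sd_uV=0.0)
        epochs = sd.gen_ssep_epochs(cfg)
        assert np.array_equal(epochs.epochs.mean(axis=0), epochs.epochs[0])

    def test_template_extrema_match_config(self):
        cfg = sd.SSEPSimConfig(noise_sd_uV=0.0)
        tpl = sd.ssep_template(cfg)
        assert tpl.max() == pytest.approx(340.0, rel=0.001)
        assert tpl.min() == pytest.approx(-178.1, rel=0.001)

    def test_epoch_average_noise_floor_scales_as_sqrt_n(self):
        # residual SD of (mean epoch - template) ~ noise_sd / sqrt(n)
        tpl = sd.ssep_template(sd.SSEPSimConfig(noise_sd_uV=0.0))
        resid = [
            (sd.gen_ssep_epochs(sd.SSEPSimConfig(seed=s)).epochs.mean(axis=0) - tpl).std()
            for s in range(6)
        ]
        expected = 30.0 / np.sqrt(90)
        assert np.mean(resid) == pytest.approx(expected, rel=0.2)

    def test_window_shorter_than_n1_latency_rejected(self):
        with pytest.raises(ValueError):
            sd.SSEPSimConfig(epoch_window_s=0.010)  # < 15 ms N1 latency

    def test_n1_must_follow_p1(self):
        with pytest.raises(ValueError):
            sd.SSEPSimConfig(p1_latency_ms=10.0, n1_latency_ms=9.0)


class TestStimTrace:
    def test_noiseless_plateau_arithmetic(self):
        tr = sd.gen_stim_trace(100.0, 1.28, noise_sd=0.0)
        t = tr.times_s
        stim = (t >= 10.0) & (t < 50.0)
        assert np.all(tr.values[stim] == pytest.approx(128.0))
        assert np.all(tr.values[~stim] == pytest.approx(100.0))

    def test_unit_ratio_gives_flat_trace(self):
        tr = sd.gen_stim_trace(100.0, 1.0, noise_sd=0.0)
        assert np.all(tr.values == 100.0)

    def test_noisy_plateau_ratio_recovered_within_one_percent(self):
        tr = sd.gen_stim_trace(100.0, 1.28, noise_sd=2.0, seed=0)
        t = tr.times_s
        pre = tr.values[t < 10.0].mean()
        stim = tr.values[(t >= 10.0) & (t < 50.0)].mean()
        assert stim / pre == pytest.approx(1.28, rel=0.01)

    def test_non_positive_durations_rejected(self):
        with pytest.raises(ValueError):
            sd.gen_stim_trace(100.0, 1.28, pre_s=0.0)
        with pytest.raises(ValueError):
            sd.gen_stim_trace(100.0, -1.0)


class TestGlucoseGenerator:
    def test_flat_profile(self):
        cfg = sd.GlucoseSimConfig(fasting_level=100.0, peak_level=100.0, noise_sd=0.0)
        s = sd.gen_glucose_table(cfg)
        assert np.all(s.values_mg_dl == 100.0)

    def test_peak_at_first_postload_timepoint(self):
        cfg = sd.GlucoseSimConfig(fasting_level=109.5, peak_level=280.0, noise_sd=0.0)
        s = sd.gen_glucose_table(cfg)
        assert s.times_min[np.argmax(s.values_mg_dl)] == 30.0
        assert np.all(np.diff(s.values_mg_dl[1:]) < 0)  # monotone decay after peak

    def test_auc_ordering_follows_peak_ordering(self):
        # trapezoid oracle: higher peak, same everything else -> larger AUC
        lo = sd.gen_glucose_table(sd.GlucoseSimConfig(peak_level=200.0, noise_sd=0.0))
        hi = sd.gen_glucose_table(sd.GlucoseSimConfig(peak_level=300.0, noise_sd=0.0))
        auc = lambda s: np.trapezoid(s.values_mg_dl, s.times_min)
        assert auc(hi) > auc(lo)

    def test_seed_reproducible(self):
        cfg = sd.GlucoseSimConfig(seed=7, noise_sd=10.0)
        a = sd.gen_glucose_table(cfg)
        b = sd.gen_glucose_table(cfg)
        assert np.array_equal(a.values_mg_dl, b.values_mg_dl)
        assert a.values_mg_dl[1] == pytest.approx(252.9874553750847, abs=1e-9)

    def test_non_increasing_timepoints_rejected(self):
        with pytest.raises(ValueError):
            sd.GlucoseSimConfig(timepoints_min=(0.0, 30.0, 30.0, 120.0))
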