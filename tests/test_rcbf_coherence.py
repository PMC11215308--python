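"""ROI extraction, rCBF normalization, stimulation response, and the
coherence / phase-lag analysis of slow vasomotion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neurovasc import rcbf_coherence as rc
from neurovasc import synthetic_data as sd
from neurovasc.core import FlowMovie, ROISpec, ROITrace


def movie_from(frames):
    return FlowMovie(frames=np.asarray(frames, dtype=float),
                     frame_rate_hz=2.0, pixel_size_mm=0.1)


class TestExtractROITrace:
    def test_constant_movie_yields_constant_trace(self):
        movie = movie_from(np.full((10, 12, 12), 7.0))
        tr = rc.extract_roi_trace(movie, ROISpec((0.6, 0.6), 0.35))
        assert np.all(tr.values == 7.0)

    def test_sub_pixel_roi_equals_single_pixel_series(self):
        frames = np.random.default_rng(0).uniform(1, 2, (20, 8, 8))
        movie = movie_from(frames)
        # center of pixel (row 3, col 5) is (0.55, 0.35) mm at 0.1 mm/px
        tr = rc.extract_roi_trace(movie, ROISpec((0.55, 0.35), 0.04))
        assert np.array_equal(tr.values, frames[:, 3, 5])

    def test_gradient_roi_matches_brute_force_enumeration(self):
        rows, cols = 15, 18
        frames = (np.arange(rows)[:, None] * 10.0 + np.arange(cols)[None, :])[None]
        frames = np.repeat(frames, 3, axis=0)
        movie = movie_from(frames)
        roi = ROISpec((0.93, 0.71), 0.42)
        # independent oracle: enumerate every pixel center explicitly
        acc, n = 0.0, 0
        for i in range(rows):
            for j in range(cols):
                x, y = (j + 0.5) * 0.1, (i + 0.5) * 0.1
                if (x - 0.93) ** 2 + (y - 0.71) ** 2 <= 0.42**2:
                    acc += frames[0, i, j]
                    n += 1
        tr = rc.extract_roi_trace(movie, roi)
        assert n > 0
        assert tr.values[0] == pytest.approx(acc / n, rel=1e-12)

    def test_roi_outside_field_rejected(self):
        movie = movie_from(np.ones((3, 5, 5)))
        with pytest.raises(ValueError):
            rc.extract_roi_trace(movie, ROISpec((10.0, 10.0), 0.1))


class TestNormalizeRCBF:
    def test_constant_trace_normalizes_to_one(self):
        tr = ROITrace(np.full(200, 55.0), 2.0)
        nt = rc.normalize_rcbf(tr, (0.0, 60.0))
        assert np.all(nt.rcbf_n == 1.0)
        assert nt.baseline_value == 55.0

    def test_ratio_arithmetic(self):
        values = np.concatenate([np.full(120, 100.0), np.full(80, 128.0)])
        nt = rc.normalize_rcbf(ROITrace(values, 2.0), (0.0, 60.0))
        assert np.all(nt.rcbf_n[120:] == pytest.approx(1.28))

    def test_inverse_identity_reconstructs_input(self):
        rng = np.random.default_rng(3)
        values = rng.uniform(50, 150, 300)
        tr = ROITrace(values, 2.0)
        nt = rc.normalize_rcbf(tr, (10.0, 40.0))
        assert np.allclose(nt.rcbf_n * nt.baseline_value, values)

    def test_baseline_mean_of_output_is_one(self):
        rng = np.random.default_rng(4)
        nt = rc.normalize_rcbf(ROITrace(rng.uniform(80, 120, 500), 2.0), (0.0, 100.0))
        assert nt.rcbf_n[:200].mean() == pytest.approx(1.0, abs=1e-12)

    @settings(deadline=None, max_examples=25)
    @given(scale=st.floats(0.01, 1000.0))
    def test_invariant_to_positive_rescaling(self, scale):
        values = np.sin(np.linspace(0, 6, 100)) + 5.0
        a = rc.normalize_rcbf(ROITrace(values, 2.0), (0.0, 10.0))
        b = rc.normalize_rcbf(ROITrace(values * scale, 2.0), (0.0, 10.0))
        assert np.allclose(a.rcbf_n, b.rcbf_n, rtol=1e-9)

    def test_non_positive_baseline_rejected(self):
        tr = ROITrace(np.concatenate([np.zeros(50), np.ones(50)]), 2.0)
        with pytest.raises(ValueError, match="baseline"):
            rc.normalize_rcbf(tr, (0.0, 20.0))


class TestStimResponse:
    def test_flat_trace_gives_unity(self):
        nt = rc.normalize_rcbf(ROITrace(np.full(120, 90.0), 2.0), (0.0, 10.0))
        resp = rc.stim_response(nt, (10.0, 40.0))
        assert resp.normalized_stim_mean == 1.0

    @pytest.mark.parametrize("ratio", [1.28, 1.06])
    def test_noiseless_plateau_ratio_recovered_exactly(self, ratio):
        tr = sd.gen_stim_trace(100.0, ratio, noise_sd=0.0)
        nt = rc.normalize_rcbf(tr, (0.0, 10.0))
        resp = rc.stim_response(nt, (10.0, 40.0))
        assert resp.normalized_stim_mean == pytest.approx(ratio, abs=1e-9)

    def test_overlapping_windows_rejected(self):
        nt = rc.normalize_rcbf(ROITrace(np.full(120, 90.0), 2.0), (0.0, 10.0))
        with pytest.raises(ValueError):
            rc.stim_response(nt, (5.0, 40.0))


class TestComputeCoherence:
    def test_self_coherence_is_one(self):
        rng = np.random.default_rng(0)
        tr = ROITrace(rng.standard_normal(4096) + 100.0, 2.0)
        spec = rc.compute_coherence(tr, tr)
        finite = np.isfinite(spec.coherence)
        assert np.allclose(spec.coherence[finite][1:], 1.0, atol=1e-9)

    def test_independent_noise_has_low_band_coherence(self):
        rng = np.random.default_rng(1)
        a = ROITrace(rng.standard_normal(4800) + 100.0, 2.0)
        m = ROITrace(rng.standard_normal(4800) + 100.0, 2.0)
        spec = rc.compute_coherence(a, m)
        band = (spec.freqs_hz >= 0.05) & (spec.freqs_hz <= 0.15)
        assert np.nanmean(spec.coherence[band]) < 0.2

    def test_common_sinusoid_produces_high_coherence_at_its_frequency(self):
        rng = np.random.default_rng(2)
        t = np.arange(4800) / 2.0
        s = np.sin(2 * np.pi * 0.1 * t)  # SNR 1: signal sd ~ noise sd
        a = ROITrace(100 + s + rng.standard_normal(t.size) * s.std(), 2.0)
        m = ROITrace(100 + s + rng.standard_normal(t.size) * s.std(), 2.0)
        spec = rc.compute_coherence(a, m)
        idx = np.argmin(np.abs(spec.freqs_hz - 0.1))
        assert spec.coherence[idx] > 0.9

    def test_coherence_bounded_and_scale_invariant(self):
        a, m = sd.gen_vasomotion_pair(seed=5, delay_s=1.0)
        s1 = rc.compute_coherence(a, m)
        ok = np.isfinite(s1.coherence)
        assert np.all(s1.coherence[ok] >= 0.0) and np.all(s1.coherence[ok] <= 1.0)
        a2 = ROITrace(a.values * 3.7, a.sampling_rate_hz)
        m2 = ROITrace(m.values * 0.21, m.sampling_rate_hz)
        s2 = rc.compute_coherence(a2, m2)
        assert np.allclose(s1.coherence[ok], s2.coherence[ok], atol=1e-9)

    def test_mismatched_traces_rejected(self):
        a = ROITrace(np.ones(1000) + np.arange(1000) % 3, 2.0)
        b = ROITrace(a.values[:900], 2.0)
        with pytest.raises(ValueError):
            rc.compute_coherence(a, b)


class TestBandPhaseLag:
    def test_identical_traces_have_zero_phase_and_lag(self):
        rng = np.random.default_rng(3)
        tr = ROITrace(rng.standard_normal(4096) + 100.0, 2.0)
        lag = rc.band_phase_lag(rc.compute_coherence(tr, tr))
        assert lag.phase_rad == pytest.approx(0.0, abs=1e-9)
        assert lag.lag_s == pytest.approx(0.0, abs=1e-9)
        assert lag.valid

    def test_known_delay_recovered_and_sign_convention(self):
        # A leads M by 2 s -> positive phase / positive lag
        a, m = sd.gen_vasomotion_pair(delay_s=2.0, seed=0)
        lag = rc.band_phase_lag(rc.compute_coherence(a, m))
        assert lag.valid
        assert abs(lag.lag_s - 2.0) < 0.5  # one frame interval at 2 fps
        assert lag.phase_rad > 0
        # independent oracle: cross-correlation argmax on the raw traces
        av = a.values - a.values.mean()
        mv = m.values - m.values.mean()
        xc = np.correlate(mv, av, mode="full")
        shift = (np.argmax(xc) - (av.size - 1)) / 2.0
        assert abs(shift - 2.0) <= 0.5
        assert abs(lag.lag_s - shift) <= 0.5

    def test_lag_recovery_across_delays(self):
        # band-limited signals, known delay 0.5-4 s: within one frame
        # interval in >= 95% of seeded trials
        hits = trials = 0
        for d in (0.5, 1.5, 2.5, 4.0):
            for seed in range(5):
                a, m = sd.gen_vasomotion_pair(delay_s=d, seed=seed)
                lag = rc.band_phase_lag(rc.compute_coherence(a, m))
                hits += abs(lag.lag_s - d) < 0.5
                trials += 1
        assert hits / trials >= 0.95

    def test_low_coherence_flagged_invalid(self):
        rng = np.random.default_rng(9)
        a = ROITrace(rng.standard_normal(4800) + 100.0, 2.0)
        m = ROITrace(rng.standard_normal(4800) + 100.0, 2.0)
        with pytest.warns(UserWarning, match="below threshold"):
            lag = rc.band_phase_lag(rc.compute_coherence(a, m))
        assert not lag.valid
        assert lag.mean_band_coherence < 0.5

    def test_band_with_no_bins_rejected(self):
        rng = np.random.default_rng(10)
        tr = ROITrace(rng.standard_normal(4096) + 100.0, 2.0)
        spec = rc.compute_coherence(tr, tr)
        with pytest.raises(ValueError):
            rc.band_phase_lag(spec, band_hz=(0.0501, 0.0502))

    def test_phase_times_frequency_consistent_with_lag_definition(self):
        # dt(f) * 2*pi*f reproduces the unwrapped phase at every in-band bin
        a, m = sd.gen_vasomotion_pair(delay_s=3.0, seed=2)
        spec = rc.compute_coherence(a, m)
        band = (spec.freqs_hz >= 0.05) & (spec.freqs_hz <= 0.15)
        phase = np.unwrap(spec.cross_phase_rad[band])
        dt = phase / (2 * np.pi * spec.freqs_hz[band])
        assert np.allclose(dt * 2 * np.pi * spec.freqs_hz[band], phase, atol=1e-12)
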