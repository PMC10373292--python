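import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rotormap.datatypes import ConfigurationError, FluorescenceMovie
from rotormap.preprocess import (
    FilterSpec,
    bandpass_movie,
    bandpass_trace,
    preprocess_movie,
    sliding_window_normalize,
    smooth_recompose,
    spatial_gaussian,
    untrusted_frames,
)


def movie_from(frames, mask=None):
    return FluorescenceMovie(frames, frame_interval_ms=5.0, mask=mask)


def brute_force_window_minmax(x, window):
    """Independent oracle: explicit min/max over the truncated centred
    window (even windows take one extra sample from the past)."""
    out = np.empty_like(x, dtype=float)
    half_lo = window // 2
    half_hi = (window - 1) // 2
    for i in range(x.size):
        w = x[max(0, i - half_lo) : min(x.size, i + half_hi + 1)]
        lo, hi = w.min(), w.max()
        out[i] = 0.0 if hi == lo else (x[i] - lo) / (hi - lo)
    return out


class TestSlidingWindowNormalize:
    def test_constant_trace_maps_to_zero(self):
        m = movie_from(np.full((20, 4, 4), 7.0))
        out = sliding_window_normalize(m, 10)
        assert np.all(out.frames == 0.0)

    def test_affine_invariance(self):
        rng = np.random.default_rng(0)
        f = rng.normal(size=(30, 4, 4))
        a = sliding_window_normalize(movie_from(f), 10).frames
        b = sliding_window_normalize(movie_from(3.0 * f + 11.0), 10).frames
        assert np.allclose(a, b)

    def test_square_wave_against_brute_force(self):
        x = np.tile([10.0, 10.0, 20.0, 20.0], 10)
        frames = np.tile(x[:, None, None], (1, 2, 2))
        out = sliding_window_normalize(movie_from(frames), 8).frames[:, 0, 0]
        expect = brute_force_window_minmax(x, 8)
        assert np.allclose(out, expect)
        interior = out[8:-8]
        assert set(np.round(interior, 12)) <= {0.0, 1.0}

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.integers(0, 2**32 - 1), st.integers(2, 12))
    def test_output_in_unit_interval_matches_oracle(self, seed, window):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=40)
        frames = np.tile(x[:, None, None], (1, 2, 2))
        out = sliding_window_normalize(movie_from(frames), window).frames[:, 0, 0]
        assert np.all((out >= 0) & (out <= 1))
        assert np.allclose(out, brute_force_window_minmax(x, window))

    def test_window_exceeding_length_raises(self):
        with pytest.raises(ConfigurationError):
            sliding_window_normalize(movie_from(np.zeros((5, 2, 2))), 10)


class TestSpatialGaussian:
    def test_sigma_zero_identity(self):
        rng = np.random.default_rng(1)
        m = movie_from(rng.normal(size=(3, 8, 8)))
        out = spatial_gaussian(m, 0.0)
        assert np.array_equal(out.frames, m.frames)

    def test_uniform_frame_preserved_with_mask(self):
        mask = np.zeros((16, 16), bool)
        mask[4:12, 4:12] = True
        m = movie_from(np.full((2, 16, 16), 3.5), mask=mask)
        out = spatial_gaussian(m, 2.0)
        assert np.allclose(out.frames[:, mask], 3.5, atol=1e-9)

    def test_single_pixel_mass_preserved(self):
        frames = np.zeros((2, 33, 33))
        frames[:, 16, 16] = 5.0
        out = spatial_gaussian(movie_from(frames), 2.0)
        # direct-summation oracle: total mass of an interior impulse
        assert abs(out.frames[0].sum() - 5.0) / 5.0 < 1e-6

    def test_masked_pixels_do_not_leak(self):
        mask = np.ones((9, 9), bool)
        mask[4, 4] = False
        frames = np.zeros((2, 9, 9))
        frames[:, 4, 4] = 100.0  # masked-out hot pixel must not contribute
        out = spatial_gaussian(movie_from(frames, mask=mask), 1.5)
        assert np.all(np.abs(out.frames[:, mask]) < 1e-9)


class TestBandpass:
    fs = 200.0

    def test_tone_amplitude_and_zero_lag(self):
        t = np.arange(0, 10, 1 / self.fs)
        x = np.sin(2 * np.pi * 10.0 * t)
        y = bandpass_trace(x, self.fs)
        mid = slice(x.size // 4, 3 * x.size // 4)
        # FFT oracle on the interior (taper-free) section
        amp_in = np.abs(np.fft.rfft(x[mid]))
        amp_out = np.abs(np.fft.rfft(y[mid]))
        k = np.argmax(amp_in)
        assert abs(amp_out[k] / amp_in[k] - 1) < 0.02
        # zero-phase check needs an aperiodic band-limited signal (a pure
        # tone has equal correlation peaks at every period)
        z = sum(np.sin(2 * np.pi * f * t + p) for f, p in [(4.0, 0.3), (7.3, 1.1), (13.1, 2.0)])
        zy = bandpass_trace(z, self.fs)
        lags = np.arange(-50, 51)
        xc = [np.dot(z[mid], np.roll(zy, L)[mid]) for L in lags]
        assert lags[int(np.argmax(xc))] == 0

    def test_drift_attenuated(self):
        t = np.arange(0, 10, 1 / self.fs)
        drift = np.sin(2 * np.pi * 0.1 * t)
        y = bandpass_trace(drift, self.fs)
        mid = slice(x1 := t.size // 4, 3 * t.size // 4)
        a_in = np.abs(np.fft.rfft(drift[mid]))
        a_out = np.abs(np.fft.rfft(y[mid]))
        k = np.argmax(a_in)
        assert a_out[k] / a_in[k] < 0.05

    def test_zero_input_zero_output(self):
        assert np.allclose(bandpass_trace(np.zeros(500), self.fs), 0.0)

    def test_band_above_nyquist_rejected(self):
        m = movie_from(np.zeros((50, 2, 2)))
        with pytest.raises(ConfigurationError):
            bandpass_movie(m, FilterSpec(band_high_hz=150.0))

    def test_untrusted_frames_count(self):
        flags = untrusted_frames(2000, 200.0, 1.0)
        assert flags[:400].all() and flags[-400:].all()
        assert not flags[400:-400].any()


class TestSmoothRecompose:
    fs = 200.0

    def test_sum_of_k_sinusoids_exact(self):
        t = np.arange(0, 5, 1 / self.fs)
        x = np.zeros_like(t)
        for f in (2.0, 5.0, 11.0):  # bins of the 5 s window, in band
            x += np.sin(2 * np.pi * f * t)
        out, resid = smooth_recompose(x, self.fs, n_components=3)
        assert resid < 1e-8
        assert np.allclose(out, x, atol=1e-6)

    def test_k1_picks_dominant_component(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=1000)
        out, _ = smooth_recompose(x, self.fs, n_components=1)
        spec = np.fft.rfft(x)
        freqs = np.fft.rfftfreq(x.size, 1 / self.fs)
        in_band = (freqs >= 1) & (freqs <= 30)
        k = np.argmax(np.where(in_band, np.abs(spec), -1))
        expect = np.zeros_like(spec)
        expect[k] = spec[k]
        assert np.allclose(out, np.fft.irfft(expect, x.size))

    def test_invalid_k(self):
        with pytest.raises(ConfigurationError):
            smooth_recompose(np.zeros(100), self.fs, n_components=0)


class TestChain:
    def test_deterministic_and_provenance_ordered(self):
        rng = np.random.default_rng(3)
        frames = rng.normal(size=(250, 6, 6))
        a, fa = preprocess_movie(movie_from(frames), FilterSpec(norm_window_frames=50))
        b, fb = preprocess_movie(movie_from(frames), FilterSpec(norm_window_frames=50))
        assert np.array_equal(a.frames, b.frames)
        assert np.array_equal(fa, fb)
        names = [p.split("(")[0] for p in a.provenance]
        assert names == ["sliding_window_normalize", "spatial_gaussian", "bandpass"]
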