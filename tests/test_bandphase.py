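"""DFT band-pass filtering, analytic phase/amplitude, power spectra."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from facewave import (
    Band,
    HEARTBEAT_BAND,
    SLOW_BAND,
    SceneConfig,
    TimeSeries,
    analytic,
    analytic_field,
    bandpass,
    generate_field,
    generate_probe_trace,
    power_spectrum,
)
from facewave.bandphase import movie_frame_span
from facewave.chromomap import HbOMapSequence


def _tone(f, fs=10.0, duration=100.0, phase=0.0, amp=1.0):
    t = np.arange(int(duration * fs)) / fs
    return TimeSeries(amp * np.cos(2 * np.pi * f * t + phase), fs)


class TestBandpass:
    def test_in_band_tone_passes_unchanged(self):
        ts = _tone(0.1)  # bin-aligned: 0.1 Hz on a 100 s record
        out = bandpass(ts, SLOW_BAND)
        err = np.linalg.norm(out.values - ts.values) / np.linalg.norm(ts.values)
        assert err < 1e-10

    def test_out_of_band_tone_rejected(self):
        ts = _tone(1.0)
        out = bandpass(ts, SLOW_BAND)
        assert np.linalg.norm(out.values) < 1e-10 * np.linalg.norm(ts.values)

    def test_two_tone_matches_bin_projection_oracle(self):
        # explicit projection onto the retained Fourier bins
        fs, n = 10.0, 1000
        t = np.arange(n) / fs
        x = np.sin(2 * np.pi * 0.1 * t) + 0.7 * np.sin(2 * np.pi * 1.0 * t)
        out = bandpass(TimeSeries(x, fs), SLOW_BAND)
        spec = np.fft.rfft(x - x.mean())
        freqs = np.fft.rfftfreq(n, 1 / fs)
        spec[(freqs < 0.04) | (freqs > 0.2)] = 0.0
        oracle = np.fft.irfft(spec, n=n)
        assert np.abs(out.values - oracle).max() < 1e-10

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(_tone(0.1, fs=2.0), HEARTBEAT_BAND)

    def test_empty_band_rejected(self):
        ts = _tone(0.1, duration=20.0)
        with pytest.raises(ValueError, match="no DFT bins"):
            bandpass(ts, Band(0.021, 0.039))  # between bins at df = 0.05

    def test_hamming_mode_tapers_record_edges(self):
        ts = _tone(0.1)
        out = bandpass(ts, SLOW_BAND, window="hamming")
        assert abs(out.values[0]) < 0.2 * abs(ts.values[0])

    @given(st.floats(-5, 5).filter(lambda a: abs(a) > 1e-3),
           st.floats(-5, 5).filter(lambda a: abs(a) > 1e-3))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_linearity(self, a, b):
        fs, n = 10.0, 500
        rng = np.random.default_rng(42)
        x, y = rng.normal(size=(2, n))
        fx = bandpass(TimeSeries(x, fs), SLOW_BAND).values
        fy = bandpass(TimeSeries(y, fs), SLOW_BAND).values
        fxy = bandpass(TimeSeries(a * x + b * y, fs), SLOW_BAND).values
        assert np.allclose(fxy, a * fx + b * fy, atol=1e-9)

    def test_idempotence(self, rng):
        ts = TimeSeries(rng.normal(size=800), 10.0)
        once = bandpass(ts, SLOW_BAND)
        twice = bandpass(once, SLOW_BAND)
        assert np.allclose(once.values, twice.values, atol=1e-12)

    def test_disjoint_band_partition_conserves_ac_power(self, rng):
        ts = TimeSeries(rng.normal(size=1000), 10.0)
        x = ts.values - ts.values.mean()
        bands = [Band(1e-6, 1.0), Band(1.01, 3.0), Band(3.01, 5.0)]
        parts = [bandpass(ts, b).values for b in bands]
        total = sum(np.sum(p**2) for p in parts)
        assert total == pytest.approx(np.sum(x**2), rel=1e-9)


class TestAnalytic:
    def test_cosine_amplitude_and_advancing_phase(self):
        ts = _tone(0.1, duration=200.0)
        res = analytic(ts, SLOW_BAND)
        interior = slice(200, -200)
        assert np.allclose(res.amplitude[interior], 1.0, rtol=0.01)
        # phase advances 360 deg per 10 s period
        unwrapped = np.unwrap(np.radians(res.phase[interior]))
        rate = np.mean(np.diff(unwrapped)) * ts.sample_rate
        assert rate == pytest.approx(2 * np.pi * 0.1, rel=1e-3)

    def test_quadrature_amplitude_identity(self):
        fs, n = 10.0, 2000
        t = np.arange(n) / fs
        a, b = 1.3, -0.6
        x = a * np.cos(2 * np.pi * 0.1 * t) + b * np.sin(2 * np.pi * 0.1 * t)
        res = analytic(TimeSeries(x, fs), SLOW_BAND)
        assert np.allclose(
            res.amplitude[200:-200], np.hypot(a, b), rtol=0.01
        )

    def test_am_tone_envelope_recovered(self):
        fs, duration = 10.0, 400.0
        t = np.arange(int(fs * duration)) / fs
        env = 1 + 0.5 * np.sin(2 * np.pi * 0.01 * t)
        x = env * np.cos(2 * np.pi * 0.1 * t)
        res = analytic(TimeSeries(x, fs), Band(0.04, 0.2))
        interior = slice(400, -400)
        rel = np.abs(res.amplitude[interior] - env[interior]) / env[interior]
        assert np.median(rel) < 0.02

    @given(st.floats(0.01, 100.0))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_phase_invariant_to_amplitude_scaling(self, scale):
        ts = _tone(0.1, duration=100.0)
        scaled = TimeSeries(scale * ts.values, ts.sample_rate)
        p1 = analytic(ts, SLOW_BAND).phase
        p2 = analytic(scaled, SLOW_BAND).phase
        circular_diff = (p1 - p2 + 180.0) % 360.0 - 180.0
        assert np.abs(circular_diff).max() < 1e-6


class TestAnalyticField:
    def test_plane_wave_phase_gradient(self):
        cfg = SceneConfig(
            grid_shape=(20, 20), duration=60.0, phase_velocity=4.0,
            direction=(1.0, 0.0), amp_heart=0.0, noise_sd=0.0,
        )
        maps = HbOMapSequence(generate_field(cfg).concentration, cfg.frame_rate)
        field = analytic_field(maps, SLOW_BAND)
        mid = field.phase.shape[0] // 2
        row = np.unwrap(np.radians(field.phase[mid, 10, :]))
        grad = np.abs(np.degrees(np.mean(np.diff(row)))) / cfg.pixel_pitch
        assert grad == pytest.approx(360 * 0.1 / 4.0, rel=0.02)

    def test_single_pixel_matches_trace_analytic(self):
        cfg = SceneConfig(grid_shape=(6, 6), duration=60.0, seed=9)
        maps = HbOMapSequence(generate_field(cfg).concentration, cfg.frame_rate)
        field = analytic_field(maps, SLOW_BAND, max_block_bytes=10_000)
        ts = TimeSeries(maps.concentration[:, 3, 2], cfg.frame_rate)
        single = analytic(ts, SLOW_BAND)
        assert np.allclose(field.phase[:, 3, 2], single.phase, atol=1e-9)
        assert np.allclose(field.amplitude[:, 3, 2], single.amplitude, atol=1e-12)

    def test_too_short_record_rejected(self):
        maps = HbOMapSequence(np.zeros((100, 4, 4)), 10.0)  # 10 s < 2/0.04
        with pytest.raises(ValueError, match="shorter"):
            analytic_field(maps, SLOW_BAND)


class TestPowerSpectrum:
    def test_pure_tone_peaks_at_its_frequency(self):
        freqs, power = power_spectrum(_tone(1.0, duration=100.0))
        assert freqs[np.argmax(power)] == pytest.approx(1.0, abs=0.01)

    def test_parseval_with_window_factor(self, rng):
        x = rng.normal(size=1000)
        ts = TimeSeries(x, 10.0)
        freqs, power = power_spectrum(ts)
        xd = x - x.mean()
        w = np.hamming(1000)
        expected = np.sum((w * xd) ** 2) / np.sum(w**2)
        assert power.sum() == pytest.approx(expected, rel=1e-6)

    def test_default_trace_top_two_peaks_at_slow_and_heart(self):
        cfg = SceneConfig(grid_shape=(4, 4), duration=600.0, seed=0)
        freqs, power = power_spectrum(generate_probe_trace(cfg))
        # two largest *local maxima* (window leakage spreads each peak
        # over neighbouring bins, so top-2 bins would both sit on one peak)
        interior = power[1:-1]
        peaks = np.where((interior > power[:-2]) & (interior > power[2:]))[0] + 1
        top_two = freqs[peaks[np.argsort(power[peaks])[-2:]]]
        assert sorted(np.round(top_two, 2)) == [0.1, 1.0]


def test_movie_frame_span_arithmetic():
    assert movie_frame_span(0.5, 1, 5) == pytest.approx(2.0)
    with pytest.raises(ValueError):
        movie_frame_span(0.5, 5, 1)
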