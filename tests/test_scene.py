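"""Synthetic-scene generator: wave kinematics, rendering, probe traces."""

import numpy as np
import pytest

from facewave import (
    CalibrationMatrices,
    SceneConfig,
    generate_field,
    generate_probe_trace,
    render_rgb,
)
from facewave.scene import GamutError, GRAYCARD_ROWS


def _quiet(**kw) -> SceneConfig:
    base = dict(
        grid_shape=(16, 16), duration=40.0, amp_slow=0.0, amp_heart=0.0,
        noise_sd=0.0, baseline=1.0,
    )
    base.update(kw)
    return SceneConfig(**base)


class TestGenerateField:
    def test_degenerate_scene_is_constant_baseline(self):
        field = generate_field(_quiet(baseline=2.5))
        assert np.all(field.concentration == 2.5)

    def test_half_wavelength_separation_is_in_antiphase(self):
        # c = 4 mm/s at 0.1 Hz -> wavelength 40 mm; pixels 20 mm apart along
        # the propagation direction oscillate 180 deg out of phase.
        cfg = SceneConfig(
            grid_shape=(4, 60), pixel_pitch=0.5, duration=40.0,
            phase_velocity=4.0, direction=(1.0, 0.0), amp_heart=0.0,
            noise_sd=0.0,
        )
        conc = generate_field(cfg).concentration
        near, far = conc[:, 0, 0], conc[:, 0, 40]  # 40 px * 0.5 mm = 20 mm
        assert np.allclose(near, -far, atol=1e-9)

    def test_default_pixel_spectrum_peaks_at_slow_and_heart_frequencies(self):
        # brute-force DFT of one pixel's trace; top two peaks at 0.1 and 1 Hz
        cfg = SceneConfig(grid_shape=(8, 8), duration=120.0, seed=0)
        trace = generate_field(cfg).concentration[:, 4, 4]
        spec = np.abs(np.fft.rfft(trace - trace.mean())) ** 2
        freqs = np.fft.rfftfreq(trace.size, d=1.0 / cfg.frame_rate)
        top_two = freqs[np.argsort(spec)[-2:]]
        assert sorted(np.round(top_two, 2)) == [0.1, 1.0]

    def test_fixed_seed_is_bitwise_reproducible(self):
        cfg = SceneConfig(grid_shape=(8, 8), duration=30.0, seed=7)
        a = generate_field(cfg).concentration
        b = generate_field(SceneConfig(grid_shape=(8, 8), duration=30.0, seed=7)).concentration
        assert np.array_equal(a, b)

    def test_epoch_gating_silences_slow_wave_outside_epochs(self):
        cfg = SceneConfig(
            grid_shape=(4, 4), duration=100.0, amp_heart=0.0, noise_sd=0.0,
            epochs=[(30.0, 60.0)],
        )
        conc = generate_field(cfg).concentration
        t = cfg.times
        assert np.allclose(conc[t < 29.0], 0.0, atol=1e-12)
        assert np.allclose(conc[t > 61.0], 0.0, atol=1e-12)
        active = conc[(t > 35.0) & (t < 55.0)]
        assert np.ptp(active) > cfg.amp_slow  # full swing inside the epoch

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"phase_velocity": -1.0},
            {"duration": 10.0},  # < 2 / f_slow
            {"frame_rate": 1.5},  # below 2 * f_heart
            {"direction": (0.0, 0.0)},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SceneConfig(grid_shape=(8, 8), **kwargs)


class TestRenderRGB:
    def test_static_scene_renders_identical_frames(self, calib):
        video = render_rgb(generate_field(_quiet()), calib)
        assert np.all(video.frames == video.frames[0])

    def test_graycard_strip_appended(self, calib):
        cfg = _quiet()
        video = render_rgb(generate_field(cfg), calib, cfg)
        r0, r1, c0, c1 = video.graycard_region
        assert (r1 - r0, c1 - c0) == (GRAYCARD_ROWS, cfg.grid_shape[1])
        card = video.frames[:, r0:r1, c0:c1]
        assert np.all(card == card[0, 0, 0])

    def test_quantization_leaves_a_noise_floor(self, calib):
        # with 8-bit quantization on, the estimator cannot reproduce the
        # input concentration exactly: the round-trip residual is nonzero
        from facewave import estimate_hbo, rgb_to_xyz

        cfg = SceneConfig(grid_shape=(8, 8), duration=30.0, noise_sd=0.0,
                          amp_heart=0.0)
        field = generate_field(cfg)
        video = render_rgb(field, calib, cfg)
        maps = estimate_hbo(rgb_to_xyz(video, calib), calib, cfg.frame_rate)
        rows = cfg.grid_shape[0]
        recovered = maps.concentration[:, :rows, :]
        resid = (recovered - recovered.mean(axis=0)) - (
            field.concentration - field.concentration.mean(axis=0)
        )
        assert resid.std() > 0

    def test_gamut_clipping_raises(self, calib):
        cfg = _quiet(baseline=8.0)  # far outside the renderable family
        with pytest.raises(GamutError):
            render_rgb(generate_field(cfg), calib, cfg)

    def test_drift_corrected_render_matches_drift_free(self, calib):
        # 5% slow illumination drift + gray-card correction downstream
        # reproduces the drift-free pipeline output within the 8-bit floor
        from facewave import correct_illuminance, estimate_hbo, preprocess, rgb_to_xyz

        def run(cfg):
            video = render_rgb(generate_field(cfg), calib, cfg)
            video = correct_illuminance(video)
            video = preprocess(video)
            maps = estimate_hbo(rgb_to_xyz(video, calib), calib, video.frame_rate)
            conc = maps.concentration[:, : cfg.grid_shape[0], :]
            return conc - conc.mean(axis=0)

        base = dict(grid_shape=(12, 12), duration=60.0, noise_sd=0.0, seed=3)
        drifted = run(SceneConfig(
            **base, illum_drift=lambda t: 1 + 0.05 * np.sin(2 * np.pi * 0.01 * t)
        ))
        clean = run(SceneConfig(**base))
        assert np.abs(drifted - clean).max() < 0.08  # ~2 LSB in C units


class TestProbeTrace:
    def test_noiseless_trace_has_cycle_length_one_over_f(self):
        from facewave import cycle_length

        cfg = SceneConfig(grid_shape=(4, 4), duration=300.0, noise_sd=0.0,
                          amp_heart=0.0)
        ts = generate_probe_trace(cfg)
        res = cycle_length(ts)
        assert res.determinate
        assert res.cycle_length == pytest.approx(10.0, abs=0.1)

    def test_pure_noise_trace_runs_without_frequency_claim(self):
        from facewave import CYCLE_BAND, cycle_length

        cfg = SceneConfig(grid_shape=(4, 4), duration=300.0, amp_slow=1e-9,
                          amp_heart=0.0, noise_sd=1.0, seed=5)
        res = cycle_length(generate_probe_trace(cfg), band=CYCLE_BAND)
        assert res.verdict_reason in (
            "ok", "no_local_min", "no_local_max", "sign_condition_failed"
        )

    def test_band_power_concentrated_in_slow_band(self):
        # brute-force band power: slow band 0.04-0.2 Hz dominates 0.2-0.4 Hz
        cfg = SceneConfig(grid_shape=(4, 4), duration=300.0, seed=2)
        ts = generate_probe_trace(cfg)
        spec = np.abs(np.fft.rfft(ts.values - ts.values.mean())) ** 2
        freqs = np.fft.rfftfreq(ts.n, 1.0 / ts.sample_rate)
        in_band = spec[(freqs >= 0.04) & (freqs <= 0.2)].sum()
        above = spec[(freqs > 0.2) & (freqs <= 0.4)].sum()
        assert in_band > above

    def test_flow_kind_has_positive_baseline(self):
        cfg = SceneConfig(grid_shape=(4, 4), duration=60.0, seed=2)
        flow = generate_probe_trace(cfg, kind="flow")
        assert flow.values.min() > 0

    def test_unknown_kind_rejected(self):
        cfg = SceneConfig(grid_shape=(4, 4), duration=60.0)
        with pytest.raises(ValueError):
            generate_probe_trace(cfg, kind="velocity")
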