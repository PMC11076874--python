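"""Preprocessing chain: resampler fidelity, FIR frequency response, z-score."""

import numpy as np
import pytest
from scipy import signal as sps

from spindlecnn.preprocess import (
    PreprocessConfig,
    bandpass_fir,
    design_bandpass_fir,
    preprocess_pipeline,
    resample,
    zscore,
)
from spindlecnn.synthgen import generate_recording
from spindlecnn.types import Recording

from conftest import fast_config


def make_rec(x: np.ndarray, fs: float) -> Recording:
    return Recording(np.atleast_2d(x), fs, ["C3"][: np.atleast_2d(x).shape[0]], "S")


def tone_gain_db(cfg: PreprocessConfig, freq: float, fs: float = 100.0,
                 dur: float = 120.0) -> float:
    """Measured gain of the zero-phase filter on a pure tone (FFT/RMS)."""
    t = np.arange(int(dur * fs)) / fs
    x = np.sin(2 * np.pi * freq * t)
    y = bandpass_fir(make_rec(x, fs), cfg).signal[0]
    core = slice(int(10 * fs), int((dur - 10) * fs))  # avoid edge transients
    return 20 * np.log10(np.std(y[core]) / np.std(x[core]))


class TestResample:
    def test_sine_matches_closed_form(self):
        t = np.arange(int(60 * 1024)) / 1024
        rec = make_rec(np.sin(2 * np.pi * 5 * t), 1024)
        out = resample(rec, 100.0)
        assert out.n_samples == 6000
        ref = np.sin(2 * np.pi * 5 * np.arange(6000) / 100)
        assert np.corrcoef(out.signal[0], ref)[0, 1] >= 0.999

    def test_same_rate_is_identity(self):
        rec = make_rec(np.random.default_rng(0).standard_normal(500), 100)
        out = resample(rec, 100.0)
        np.testing.assert_array_equal(out.signal, rec.signal)

    def test_upsampling_rejected(self):
        rec = make_rec(np.zeros(100), 100)
        with pytest.raises(ValueError, match="upsampling"):
            resample(rec, 200.0)


class TestBandpassDesign:
    @pytest.fixture(scope="class")
    def cfg(self):
        return PreprocessConfig()

    def test_passband_flat_within_1db(self, cfg):
        h = design_bandpass_fir(cfg)
        w, resp = sps.freqz(h, worN=1 << 16, fs=cfg.target_fs_hz)
        band = (w >= 1.0) & (w <= 28.0)
        gains_db = 20 * np.log10(np.abs(resp[band]))
        assert gains_db.min() > -1.0 and gains_db.max() < 1.0

    def test_minus_6db_at_edges(self, cfg):
        h = design_bandpass_fir(cfg)
        w, resp = sps.freqz(h, worN=1 << 16, fs=cfg.target_fs_hz)
        for edge in cfg.band_hz:
            g = 20 * np.log10(np.abs(resp[np.argmin(np.abs(w - edge))]))
            assert abs(g - (-6.0)) < 0.3

    def test_sigma_tone_passes_unattenuated(self, cfg):
        assert abs(tone_gain_db(cfg, 13.0)) < 1.0

    def test_45hz_attenuated_40db(self, cfg):
        assert tone_gain_db(cfg, 45.0) <= -40.0

    def test_dc_removed(self, cfg):
        rec = make_rec(np.full(12000, 10.0), 100)
        out = bandpass_fir(rec, cfg)
        assert abs(out.signal[0, 2000:-2000].mean()) < 1e-3

    def test_linearity(self, cfg):
        rng = np.random.default_rng(1)
        x, y = rng.standard_normal((2, 8000))
        fx = bandpass_fir(make_rec(x, 100), cfg).signal[0]
        fy = bandpass_fir(make_rec(y, 100), cfg).signal[0]
        fxy = bandpass_fir(make_rec(2 * x - 3 * y, 100), cfg).signal[0]
        np.testing.assert_allclose(fxy, 2 * fx - 3 * fy, rtol=1e-9, atol=1e-9)

    def test_short_recording_rejected(self, cfg):
        with pytest.raises(ValueError, match="filter"):
            bandpass_fir(make_rec(np.zeros(1000), 100), cfg)

    def test_wrong_rate_rejected(self, cfg):
        with pytest.raises(ValueError, match="resample"):
            bandpass_fir(make_rec(np.zeros(10000), 256), cfg)

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError, match="band"):
            PreprocessConfig(band_hz=(30.0, 0.3))


class TestZscore:
    def test_mean_zero_sd_one(self):
        rng = np.random.default_rng(2)
        rec = Recording(5 + 3 * rng.standard_normal((2, 4000)), 100, ["C3", "C4"], "S")
        out = zscore(rec)
        for ch in range(2):
            assert abs(out.signal[ch].mean()) < 1e-10
            assert abs(out.signal[ch].std() - 1) < 1e-10

    def test_affine_invariance(self):
        x = np.random.default_rng(3).standard_normal((1, 1000))
        a = zscore(Recording(x, 100, ["C3"], "S")).signal
        b = zscore(Recording(7.5 * x - 4.2, 100, ["C3"], "S")).signal
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_zero_variance_channel_named(self):
        sig = np.vstack([np.random.default_rng(0).standard_normal(100),
                         np.zeros(100)])
        with pytest.raises(ValueError, match="C4"):
            zscore(Recording(sig, 100, ["C3", "C4"], "S"))


class TestPipeline:
    def test_composition_postconditions(self):
        rec, _ = generate_recording(
            fast_config(fs_hz=1024.0, record_duration_s=120.0, seed=4), "S"
        )
        out = preprocess_pipeline(rec, PreprocessConfig())
        assert out.fs_hz == 100.0
        assert out.n_samples == 12000
        for ch in range(out.n_channels):
            assert abs(out.signal[ch].mean()) < 1e-9
            assert abs(out.signal[ch].std() - 1) < 1e-9
        assert "bandpass" in out.meta and "zscore" in out.meta

    def test_sigma_contrast_preserved(self, preprocessed_cohort):
        """Annotated intervals keep their sigma-band dominance at 100 Hz."""
        from test_synthgen import sigma_power_fraction

        rec, ann = preprocessed_cohort[0]
        ci = 0
        ch = rec.channel_names[ci]
        mask = np.zeros(rec.n_samples, dtype=bool)
        for row in ann[ann["channel"] == ch].itertuples(index=False):
            i0 = int(row.onset_s * rec.fs_hz)
            i1 = int((row.onset_s + row.duration_s) * rec.fs_hz)
            mask[i0:i1] = True
        assert sigma_power_fraction(rec.signal[ci][mask], rec.fs_hz) > \
            sigma_power_fraction(rec.signal[ci][~mask], rec.fs_hz)
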