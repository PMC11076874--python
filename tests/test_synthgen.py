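"""Synthetic PSG generator: event statistics, spectra, reproducibility."""

import numpy as np
import pandas as pd
import pytest
from scipy import signal as sps

from spindlecnn.synthgen import (
    GeneratorConfig,
    SpindleRegime,
    generate_cohort,
    generate_recording,
    insomnia_regime,
    normal_regime,
)
from spindlecnn.types import validate_annotations

from conftest import FAST_FS, fast_config


def sigma_power_fraction(x: np.ndarray, fs: float) -> float:
    """Power in 11-16 Hz relative to 0.3-30 Hz, via Welch."""
    f, p = sps.welch(x, fs=fs, nperseg=min(len(x), 256))
    band = (f >= 11) & (f <= 16)
    total = (f >= 0.3) & (f <= 30)
    return p[band].sum() / p[total].sum()


class TestEventStatistics:
    def test_poisson_event_count(self):
        """Mean annotation count over many seeds matches rate x duration."""
        rate, dur = 3.0, 600.0
        lam = rate * dur / 60.0  # 30 expected events per channel
        n_seeds = 100
        counts = []
        for seed in range(n_seeds):
            cfg = GeneratorConfig(
                fs_hz=FAST_FS, record_duration_s=dur, spindle_rate_per_min=rate,
                channel_names=("C3",), seed=seed,
            )
            _, ann = generate_recording(cfg, "S")
            counts.append(len(ann))
        se = np.sqrt(lam / n_seeds)
        assert abs(np.mean(counts) - lam) < 3 * se

    def test_zero_rate_gives_pure_background(self):
        rec, ann = generate_recording(
            fast_config(spindle_rate_per_min=0.0), "S"
        )
        assert len(ann) == 0
        assert rec.signal.shape == (2, int(300 * FAST_FS))

    def test_event_segments_peak_in_sigma_band(self):
        """PSD peak of (signal - background) lies inside the regime band."""
        cfg = fast_config(channel_names=("C3",), seed=21)
        rec, ann = generate_recording(cfg, "S")
        rec0, _ = generate_recording(
            fast_config(channel_names=("C3",), seed=21, spindle_rate_per_min=0.0), "S"
        )
        events_only = rec.signal[0] - rec0.signal[0]
        assert len(ann) > 3
        lo, hi = cfg.regime.freq_range_hz
        for row in ann.itertuples(index=False):
            i0 = int(row.onset_s * FAST_FS)
            i1 = int((row.onset_s + row.duration_s) * FAST_FS)
            seg = events_only[i0:i1]
            f, p = sps.periodogram(seg, fs=FAST_FS)
            peak = f[np.argmax(p)]
            assert lo - 1.0 <= peak <= hi + 1.0

    def test_min_gap_and_bounds(self):
        cfg = fast_config(seed=13)
        rec, ann = generate_recording(cfg, "S")
        validate_annotations(ann, rec)
        for ch, grp in ann.groupby("channel"):
            onsets = grp["onset_s"].to_numpy()
            ends = onsets + grp["duration_s"].to_numpy()
            assert (onsets[1:] - ends[:-1] >= cfg.min_gap_s - 1e-9).all()

    def test_infeasible_density_rejected(self):
        with pytest.raises(ValueError, match="cannot fit"):
            GeneratorConfig(
                fs_hz=FAST_FS, record_duration_s=60.0, spindle_rate_per_min=40.0
            )


class TestSpectralContract:
    def test_sigma_fraction_higher_in_events(self):
        """Annotated intervals carry more relative sigma power than the rest."""
        rec, ann = generate_recording(fast_config(seed=5), "S")
        for ci, ch in enumerate(rec.channel_names):
            grp = ann[ann["channel"] == ch]
            mask = np.zeros(rec.n_samples, dtype=bool)
            for row in grp.itertuples(index=False):
                i0 = int(row.onset_s * rec.fs_hz)
                i1 = int((row.onset_s + row.duration_s) * rec.fs_hz)
                mask[i0:i1] = True
            ev = sigma_power_fraction(rec.signal[ci][mask], rec.fs_hz)
            bg = sigma_power_fraction(rec.signal[ci][~mask], rec.fs_hz)
            assert ev > bg


class TestReproducibilityAndCohorts:
    def test_identical_seed_bit_identical(self):
        r1, a1 = generate_recording(fast_config(seed=9), "S")
        r2, a2 = generate_recording(fast_config(seed=9), "S")
        np.testing.assert_array_equal(r1.signal, r2.signal)
        pd.testing.assert_frame_equal(a1, a2)

    def test_cohort_pairwise_distinct(self):
        cohort = generate_cohort(5, fast_config(seed=2))
        ids = [r.subject_id for r, _ in cohort]
        assert len(set(ids)) == 5
        for i in range(5):
            for j in range(i + 1, 5):
                assert not np.array_equal(cohort[i][0].signal, cohort[j][0].signal)

    def test_single_subject_cohort_matches_direct_call(self):
        from dataclasses import replace

        from spindlecnn.synthgen import derive_subject_seed

        cfg = fast_config(seed=4)
        (rec, ann), = generate_cohort(1, cfg)
        direct_rec, direct_ann = generate_recording(
            replace(cfg, seed=derive_subject_seed(4, 0)), "S01"
        )
        np.testing.assert_array_equal(rec.signal, direct_rec.signal)
        pd.testing.assert_frame_equal(ann, direct_ann)

    def test_insomnia_events_shorter_than_normal(self):
        durs = {}
        for name, regime in [("normal", normal_regime()),
                             ("insomnia", insomnia_regime())]:
            cohort = generate_cohort(3, fast_config(seed=6, regime=regime))
            durs[name] = np.concatenate(
                [a["duration_s"].to_numpy() for _, a in cohort]
            )
        assert durs["insomnia"].mean() < durs["normal"].mean()


class TestRegimeValidation:
    @pytest.mark.parametrize("kwargs", [
        {"freq_range_hz": (9.0, 16.0)},
        {"freq_range_hz": (11.0, 18.0)},
        {"duration_range_s": (0.0, 1.0)},
        {"duration_range_s": (1.5, 0.8)},
        {"envelope": "sawtooth"},
    ])
    def test_invalid_regimes_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SpindleRegime(**kwargs)

    def test_nyquist_guard(self):
        with pytest.raises(ValueError, match="twice"):
            GeneratorConfig(fs_hz=30.0)
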