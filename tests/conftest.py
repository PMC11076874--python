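"""Shared fixtures: small synthetic cohorts generated at test time."""

import numpy as np
import pytest

from spindlecnn.preprocess import PreprocessConfig, preprocess_pipeline
from spindlecnn.synthgen import (
    GeneratorConfig,
    generate_cohort,
    generate_recording,
    insomnia_regime,
)
from spindlecnn.windowing import WindowingConfig, build_window_set

#: low sampling rate keeps generation cheap; still >2x the 16 Hz sigma top
FAST_FS = 128.0


def fast_config(**kwargs) -> GeneratorConfig:
    defaults = dict(fs_hz=FAST_FS, record_duration_s=300.0,
                    spindle_rate_per_min=3.0, seed=7)
    defaults.update(kwargs)
    return GeneratorConfig(**defaults)


@pytest.fixture(scope="session")
def small_recording():
    """One 300 s two-channel recording with ~15 spindles per channel."""
    return generate_recording(fast_config(), "S01")


@pytest.fixture(scope="session")
def preprocessed_cohort():
    """Three preprocessed subjects at 100 Hz, suitable for windowing."""
    cfg = GeneratorConfig(record_duration_s=300.0, spindle_rate_per_min=4.0, seed=3)
    cohort = generate_cohort(3, cfg)
    pp = PreprocessConfig()
    return [(preprocess_pipeline(r, pp), a) for r, a in cohort]


@pytest.fixture(scope="session")
def small_window_set(preprocessed_cohort):
    return build_window_set(preprocessed_cohort, WindowingConfig(seed=5))


@pytest.fixture(scope="session")
def tiny_train_data():
    """A linearly separable toy problem shaped like real windows (n, 300)."""
    rng = np.random.default_rng(0)
    n = 256
    X = rng.standard_normal((n, 300)).astype(np.float32)
    y = rng.integers(0, 2, n)
    t = np.arange(300) / 100.0
    X[y == 1] += 3.0 * np.sin(2 * np.pi * 13.0 * t).astype(np.float32)
    return X, y
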