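"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from pals import phantom, preprocess
from pals.core_io import make_grid


def tiny_config(seed: int = 0, **overrides) -> phantom.PhantomConfig:
    """A 32 x 48 five-wavelength configuration for fast unit tests."""
    overrides.setdefault("grid", make_grid(690, 950, 65))
    overrides.setdefault("height_px", 32)
    overrides.setdefault("width_px", 48)
    overrides.setdefault("pixel_pitch_um", 788.48)
    overrides.setdefault("boundary_band_px", 2)
    overrides.setdefault("noise_sigma", 0.1)
    overrides.setdefault("spectrum_jitter_cv", 0.03)
    return phantom.default_config(seed=seed, **overrides)


@pytest.fixture()
def config() -> phantom.PhantomConfig:
    return tiny_config(seed=0)


@pytest.fixture()
def clean_config() -> phantom.PhantomConfig:
    """Noise-free, jitter-free, unit-factor configuration."""
    return tiny_config(
        seed=0,
        noise_sigma=0.0,
        spectrum_jitter_cv=0.0,
        sensitivity_amplitude=0.0,
        mu_eff=np.zeros(5),
        grueneisen=1.0,
    )


@pytest.fixture()
def frame(config):
    return phantom.make_frame(config, n_lesions=1)


@pytest.fixture()
def preprocessed_frame(config, frame):
    return preprocess.preprocess_frame(frame, config.fluence)


@pytest.fixture()
def tiny_study(config):
    return phantom.make_study(config, n_blocks=3, frames_per_block=4)


@pytest.fixture()
def preprocessed_study(config, tiny_study):
    return [preprocess.preprocess_frame(f, config.fluence) for f in tiny_study]
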