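"""Shared fixtures: small synthetic subjects generated at test time."""

from __future__ import annotations

import warnings

import pytest
from hypothesis import settings

from limbbcg.config import PipelineConfig
from limbbcg.synth import (MorphologyConfig, NoiseConfig, assemble_subject,
                           default_protocol, generate_subject,
                           make_cv_trajectories)

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")

FS = 1000.0


@pytest.fixture(scope="session")
def fs() -> float:
    return FS


@pytest.fixture(scope="session")
def morph() -> MorphologyConfig:
    return MorphologyConfig()


@pytest.fixture(scope="session")
def config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def small_protocol():
    """Nine-period protocol scaled down for fast tests (same structure)."""
    return default_protocol(duration_scale=0.2, ramp_s=5.0, cv_noise_sd=0.01)


@pytest.fixture(scope="session")
def clean_subject(small_protocol, morph):
    """Noise-free subject with ground truth (the all-purpose oracle record)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_subject(small_protocol, morph, NoiseConfig.noise_free(),
                                11, subject_id="CLEAN")


@pytest.fixture(scope="session")
def noisy_subject(small_protocol, morph):
    """Same subject at 20 dB SNR on every waveform channel."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_subject(small_protocol, morph, NoiseConfig.uniform(20.0),
                                11, subject_id="NOISY")


@pytest.fixture(scope="session")
def quiet_trajectory(small_protocol):
    return make_cv_trajectories(small_protocol, 7)
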