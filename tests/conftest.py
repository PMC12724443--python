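"""Shared fixtures: simulated sessions reused across test modules."""

from __future__ import annotations

import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from abrkit.preprocess import (
    average_by_level,
    bandpass_recording,
    epoch,
    reject_outliers,
)
from abrkit.synthesize import AbrKernelSpec, EcgSpec, SynthConfig, generate_session

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


def noiseless_config(**kwargs) -> SynthConfig:
    """A session with every stochastic component disabled: pure evoked response."""
    defaults = dict(
        seed=0,
        duration=20.0,
        background_rms=0.0,
        abr_band_noise_rms=0.0,
        channel_noise=False,
        ecg=EcgSpec(amplitude_in_abr_band=0.0),
        breathing_amplitude=0.0,
        line_noise_amplitude=0.0,
        speaker_noise_rms=1.0e-8,
    )
    defaults.update(kwargs)
    return SynthConfig(**defaults)


@pytest.fixture(scope="session")
def demo_session():
    """A one-minute default-condition session: recording, train, ground truth."""
    return generate_session(SynthConfig(seed=1, duration=60.0))


@pytest.fixture(scope="session")
def demo_averaged(demo_session):
    """The demo session taken through filtering, epoching, rejection, averaging."""
    recording, train, _ = demo_session
    filtered = bandpass_recording(recording, 300.0, 3000.0)
    tensor = epoch(filtered, train)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tensor, _ = reject_outliers(tensor)
    return average_by_level(tensor)


@pytest.fixture(scope="session")
def noiseless_session():
    return generate_session(noiseless_config())
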