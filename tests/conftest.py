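"""Shared fixtures: montage, clean/noisy synthetic subjects, tone helpers."""

import numpy as np
import pytest

from nirswave.montage_io import load_montage, remap_hemispheres
from nirswave.synthetic_data import SyntheticConfig, generate_subject

FS = 10.0


@pytest.fixture(scope="session")
def montage():
    layout, rmap = load_montage()
    return layout, rmap


@pytest.fixture(scope="session")
def region_map_left(montage):
    _, rmap = montage
    return remap_hemispheres(rmap, "left")


def quiet_config(**overrides) -> SyntheticConfig:
    """Generator config with all confounds and noise switched off."""
    base = dict(
        cardiac_amplitude=0.0,
        respiratory_amplitude=0.0,
        mayer_amplitude=0.0,
        pink_level=0.0,
        channel_noise_level=0.0,
        drift_amplitude=0.0,
        spike_rate_per_min=0.0,
        subject_amplitude_cv=0.0,
        hhb_noise_level=0.0,
    )
    base.update(overrides)
    return SyntheticConfig(**base)


@pytest.fixture(scope="session")
def default_subject():
    """One subject under the full default (noisy) study conditions."""
    return generate_subject(SyntheticConfig(seed=42), 0)


def tone(freq_hz: float, duration_s: float = 600.0, fs: float = FS,
         amplitude: float = 1.0, phase: float = 0.0) -> np.ndarray:
    t = np.arange(int(duration_s * fs)) / fs
    return amplitude * np.sin(2 * np.pi * freq_hz * t + phase)
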