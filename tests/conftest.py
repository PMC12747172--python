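"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from nirsqc.signal_io import ChannelGeometry, Recording
from nirsqc.synthetic import SimConfig, simulate_recording


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_recording(rng) -> Recording:
    """100-sample, 2-channel recording with positive random intensity."""
    intensity = 1.0 + 0.1 * rng.random((100, 2, 2))
    montage = [
        ChannelGeometry(0, 0, 30.0, False),
        ChannelGeometry(1, 1, 8.0, True),
    ]
    return Recording(
        subject_id="sub01",
        intensity=intensity,
        fs=7.812,
        montage=montage,
        age=30.0,
    )


@pytest.fixture(scope="session")
def good_subject():
    """One fully clean synthetic subject (8 channels, 300 s, HR known)."""
    cfg = SimConfig(n_subjects=1, n_channels=8, duration_s=300.0, fs=8.0, seed=42)
    rec, truth = simulate_recording(cfg, 0)
    return rec, truth, cfg


@pytest.fixture(scope="session")
def mixed_subject():
    """One subject with ~40% low-quality segments across modes."""
    cfg = SimConfig(
        n_subjects=1, n_channels=8, duration_s=300.0, fs=8.0,
        low_fraction=0.4, seed=11,
    )
    rec, truth = simulate_recording(cfg, 0)
    return rec, truth, cfg
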