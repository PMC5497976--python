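"""Shared fixtures: small synthetic corpora generated at test time."""

import numpy as np
import pytest

from scratchdetect.config import RunConfig
from scratchdetect.pipeline import PreparedCorpus, prepare_corpus
from scratchdetect.simulate import SimConfig, simulate_recording


@pytest.fixture(scope="session")
def small_sim():
    """One-minute two-channel corpus with confounders (seed 11)."""
    return simulate_recording(SimConfig(duration_s=60.0, seed=11))


@pytest.fixture(scope="session")
def small_corpus(small_sim) -> PreparedCorpus:
    """The one-minute corpus taken through calibration, detection and
    feature extraction."""
    return prepare_corpus(small_sim.audio, small_sim.truth, RunConfig())


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def tone(freq_hz: float, duration_s: float, sr: int, amplitude: float = 0.5):
    t = np.arange(int(duration_s * sr)) / sr
    return amplitude * np.sin(2 * np.pi * freq_hz * t)
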