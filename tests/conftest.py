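"""Shared fixtures: synthesized vowels and small derived datasets.

Everything is generated at test time from fixed seeds; no data files.
"""

from __future__ import annotations

import numpy as np
import pytest

from pdvoice import ChannelConfig, Phonation, default_voice_params, synthesize_phonation
from pdvoice.features import extract_cycles, preprocess


@pytest.fixture(scope="session")
def noiseless_params():
    """Perfectly periodic voice: no jitter, shimmer, noise or wander.

    F0 = 125 Hz divides the 24 kHz rate exactly, so the sampled waveform
    is exactly cycle-periodic.
    """
    return default_voice_params(
        "male", f0_mean=125.0, jitter_frac=0.0, shimmer_frac=0.0,
        aspiration_snr_db=np.inf, f0_wander_frac=0.0,
    )


@pytest.fixture(scope="session")
def noiseless_vowel(noiseless_params):
    return synthesize_phonation(noiseless_params, 24000, seed=3)


@pytest.fixture(scope="session")
def typical_vowel():
    """A realistic healthy male vowel with mild perturbations."""
    return synthesize_phonation(default_voice_params("male", f0_mean=120.0), 24000, seed=5)


@pytest.fixture(scope="session")
def typical_cycles(typical_vowel):
    return extract_cycles(preprocess(typical_vowel))


@pytest.fixture(scope="session")
def white_noise_phonation():
    rng = np.random.default_rng(12)
    return Phonation(samples=0.3 * rng.normal(size=24000 * 4), sample_rate=24000)


@pytest.fixture(scope="session")
def default_channel():
    return ChannelConfig(seed=7)
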