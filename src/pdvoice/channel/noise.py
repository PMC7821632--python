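"""Pre-coding contamination: additive white Gaussian or pink noise.

The noise realization is scaled against the *measured* clean-signal
power so the empirical SNR equals the commanded SNR by construction.
Pink noise is synthesized in the frequency domain with a 1/sqrt(f)
amplitude profile (power density falling ~3 dB per octave).
"""

from __future__ import annotations

import numpy as np

from ..phonation import Phonation

__all__ = ["add_noise", "pink_noise", "measured_snr_db"]


def pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance pink (1/f power spectrum) noise of length n."""
    white = rng.normal(size=n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    nonzero = freqs > 0
    scale[nonzero] = 1.0 / np.sqrt(freqs[nonzero])
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n)
    return x / np.std(x)


def add_noise(phonation: Phonation, kind: str, snr_db: float, seed: int = 0) -> Phonation:
    """Contaminate a phonation at an exact empirical SNR.

    The clean-signal component is left untouched; only scaled noise is
    added.  ``snr_db = +inf`` returns an identical copy.
    """
    x = phonation.samples
    p_signal = float(np.mean(x**2))
    if p_signal <= 0:
        raise ValueError("clean signal has zero power; SNR undefined")
    if np.isinf(snr_db):
        return phonation.with_samples(x.copy())
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0x11]))
    if kind == "awgn":
        noise = rng.normal(size=x.size)
    elif kind == "pink":
        noise = pink_noise(x.size, rng)
    else:
        raise ValueError("noise kind must be 'awgn' or 'pink'")
    p_target = p_signal / (10.0 ** (snr_db / 10.0))
    noise = noise * np.sqrt(p_target / float(np.mean(noise**2)))
    out = phonation.with_samples(x + noise)
    out.meta["added_noise_snr_db"] = 10.0 * np.log10(p_signal / float(np.mean(noise**2)))
    return out


def measured_snr_db(clean: np.ndarray, noisy: np.ndarray) -> float:
    """Empirical SNR of (noisy - clean) against clean, in dB."""
    noise = noisy - clean
    return float(10.0 * np.log10(np.mean(clean**2) / np.mean(noise**2)))
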