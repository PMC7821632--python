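"""Harmonicity and signal/noise-band feature families: HNR, GNE, VFER.

HNR follows the autocorrelation formulation: with r the normalized
autocorrelation at the period lag, HNR = 10 log10(r / (1 - r)) dB, and
NHR its reciprocal ratio.  GNE correlates Hilbert envelopes of 500 Hz
bands: synchronous glottal excitation drives all bands together (high
correlation) whereas turbulent noise decorrelates them.  VFER splits the
spectrum at 2.5 kHz -- below is treated as signal, above as noise -- and
forms SNR/NSR-like ratios on energy, Teager-Kaiser energy and spectral
entropy.  At the 8 kHz analysis rate used throughout, the noise band is
[2.5, 4] kHz.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import hilbert

from .cycles import CycleSequence
from .registry import GNE_FEATURES, HNR_GQ_FEATURES, VFER_FEATURES

__all__ = ["hnr_features", "gne_features", "vfer_features", "ANALYSIS_RATE"]

ANALYSIS_RATE = 8000
VFER_SPLIT_HZ = 2500.0
GNE_BANDWIDTH = 500.0


def hnr_features(cycles: CycleSequence) -> dict[str, float]:
    """HNR/NHR mean and spread over voiced frames (dB / ratio)."""
    if not cycles.voiced:
        raise ValueError("HNR requires voiced input")
    r = np.clip(cycles.frame_r, 1e-6, 1.0 - 1e-6)
    r = r[r > 0.05]
    hnr = 10.0 * np.log10(r / (1.0 - r))
    nhr = (1.0 - r) / r
    names = HNR_GQ_FEATURES[:4]
    return dict(zip(names, [
        float(np.mean(hnr)), float(np.std(hnr)),
        float(np.mean(nhr)), float(np.std(nhr)),
    ]))


def _bandpass_fft(x: np.ndarray, fs: int, lo: float, hi: float) -> np.ndarray:
    spec = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(x.size, 1.0 / fs)
    mask = (freqs >= lo) & (freqs < hi)
    spec = spec * mask
    return np.fft.irfft(spec, x.size)


def _teager(x: np.ndarray) -> np.ndarray:
    return x[1:-1] ** 2 - x[:-2] * x[2:]


def _entropy(x: np.ndarray, bins: int = 64) -> float:
    """Shannon entropy (nats) of the amplitude distribution of x."""
    if np.allclose(x, 0):
        return 0.0
    hist, _ = np.histogram(x, bins=bins)
    p = hist / hist.sum()
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)))


def gne_features(x: np.ndarray, fs: int) -> dict[str, float]:
    """Glottal-to-noise excitation measures from 500 Hz band envelopes."""
    n_bands = int((fs / 2) // GNE_BANDWIDTH)
    envs = []
    for k in range(n_bands):
        lo = k * GNE_BANDWIDTH
        hi = lo + GNE_BANDWIDTH
        band = _bandpass_fft(x, fs, max(lo, 50.0), hi)
        envs.append(np.abs(hilbert(band)))
    envs_arr = np.vstack(envs)

    # max cross-correlation between non-adjacent band envelopes
    corrs = []
    for i in range(n_bands):
        best = 0.0
        for j in range(n_bands):
            if abs(i - j) < 2:
                continue
            c = np.corrcoef(envs_arr[i], envs_arr[j])[0, 1]
            best = max(best, float(c))
        corrs.append(best)
    corrs_arr = np.asarray(corrs)

    # signal = low bands (below the 2.5 kHz split), noise = bands above
    split_band = int(VFER_SPLIT_HZ // GNE_BANDWIDTH)
    sig = envs_arr[:split_band].sum(axis=0)
    noi = envs_arr[split_band:].sum(axis=0) if n_bands > split_band else np.full_like(sig, 1e-12)
    seo_s, seo_n = float(np.mean(sig**2)), float(np.mean(noi**2)) + 1e-12
    tk_s = float(np.mean(np.abs(_teager(sig))))
    tk_n = float(np.mean(np.abs(_teager(noi)))) + 1e-12
    return dict(zip(GNE_FEATURES, [
        float(np.mean(corrs_arr)),
        float(np.std(corrs_arr)),
        10.0 * np.log10(tk_s / tk_n),
        10.0 * np.log10(seo_s / seo_n),
        tk_n / (tk_s + 1e-12),
        seo_n / (seo_s + 1e-12),
    ]))


def vfer_features(x: np.ndarray, fs: int) -> dict[str, float]:
    """Vocal-fold excitation ratios across the 2.5 kHz signal/noise split."""
    low = _bandpass_fft(x, fs, 0.0, VFER_SPLIT_HZ)
    high = _bandpass_fft(x, fs, VFER_SPLIT_HZ, fs / 2.0)

    e_low = float(np.mean(low**2))
    e_high = float(np.mean(high**2)) + 1e-15
    tk_low = float(np.mean(np.abs(_teager(low))))
    tk_high = float(np.mean(np.abs(_teager(high)))) + 1e-15
    h_low = _entropy(low) + 1e-12
    h_high = _entropy(high) + 1e-12

    # per-band energy ratio sequence over 500 Hz sub-bands (summary stats)
    n_bands = int((fs / 2) // GNE_BANDWIDTH)
    band_e = []
    for k in range(n_bands):
        b = _bandpass_fft(x, fs, k * GNE_BANDWIDTH, (k + 1) * GNE_BANDWIDTH)
        band_e.append(float(np.mean(b**2)))
    band_e_arr = np.asarray(band_e) / (sum(band_e) + 1e-15)
    p = band_e_arr[band_e_arr > 0]
    band_entropy = float(-np.sum(p * np.log(p)))

    return dict(zip(VFER_FEATURES, [
        e_low / (e_low + e_high),
        float(np.std(band_e_arr)),
        band_entropy,
        10.0 * np.log10(tk_low / tk_high),
        10.0 * np.log10(e_low / e_high),
        h_low / h_high,
        tk_high / (tk_low + 1e-15),
        e_high / (e_low + 1e-15),
        h_high / h_low,
    ]))
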