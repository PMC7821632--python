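"""Mel-frequency cepstral coefficient summaries.

Frame-based MFCC analysis with speaker-recognition defaults: 25 ms
frames, 10 ms hop, 26 triangular mel filters, DCT-II, coefficients 0-12
plus the frame log energy.  Static, delta and delta-delta sequences are
each summarized by their mean over frames, giving 14 x 3 = 42 features.
Cepstral coefficients 1-12 are invariant to uniform gain; the log-energy
feature shifts by the log of the squared gain.
"""

from __future__ import annotations

import numpy as np
from scipy.fft import dct

from .registry import MFCC_FEATURES

__all__ = ["mfcc_family"]

_FRAME_S = 0.025
_HOP_S = 0.010
_N_FILTERS = 26
_N_CEPS = 13
_PREEMPH = 0.97
_DELTA_N = 2


def _hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f) / 700.0)


def _mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m) / 2595.0) - 1.0)


def _mel_filterbank(fs: int, nfft: int, n_filters: int) -> np.ndarray:
    mel_pts = np.linspace(_hz_to_mel(0.0), _hz_to_mel(fs / 2.0), n_filters + 2)
    hz_pts = _mel_to_hz(mel_pts)
    bins = np.floor((nfft + 1) * hz_pts / fs).astype(int)
    fb = np.zeros((n_filters, nfft // 2 + 1))
    for i in range(n_filters):
        l, c, r = bins[i], bins[i + 1], bins[i + 2]
        if c == l:
            c += 1
        if r == c:
            r += 1
        fb[i, l:c] = (np.arange(l, c) - l) / (c - l)
        fb[i, c:r] = (r - np.arange(c, r)) / (r - c)
    return fb


def _deltas(c: np.ndarray, n: int = _DELTA_N) -> np.ndarray:
    """Standard regression deltas along the frame axis."""
    padded = np.pad(c, ((n, n), (0, 0)), mode="edge")
    denom = 2.0 * sum(k * k for k in range(1, n + 1))
    out = np.zeros_like(c)
    for k in range(1, n + 1):
        out += k * (padded[n + k: n + k + c.shape[0]] - padded[n - k: n - k + c.shape[0]])
    return out / denom


def mfcc_family(samples: np.ndarray, fs: int) -> dict[str, float]:
    """42 MFCC summary features from a (preprocessed) waveform."""
    x = np.asarray(samples, dtype=float)
    x = np.append(x[0], x[1:] - _PREEMPH * x[:-1])
    frame = int(round(_FRAME_S * fs))
    hop = int(round(_HOP_S * fs))
    n_frames = 1 + max(0, (x.size - frame) // hop)
    idx = np.arange(frame)[None, :] + hop * np.arange(n_frames)[:, None]
    frames = x[idx] * np.hamming(frame)

    nfft = int(2 ** np.ceil(np.log2(frame)))
    power = np.abs(np.fft.rfft(frames, nfft, axis=1)) ** 2 / nfft
    fb = _mel_filterbank(fs, nfft, _N_FILTERS)
    mel_energy = np.log(np.maximum(power @ fb.T, 1e-30))
    ceps = dct(mel_energy, type=2, axis=1, norm="ortho")[:, :_N_CEPS]
    log_e = np.log(np.maximum(np.sum(frames**2, axis=1), 1e-30))

    static = np.column_stack([log_e, ceps])              # frames x 14
    d1 = _deltas(static)
    d2 = _deltas(d1)
    values = np.concatenate([static.mean(axis=0), d1.mean(axis=0), d2.mean(axis=0)])
    return dict(zip(MFCC_FEATURES, values.tolist()))
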