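"""Empirical mode decomposition and EMD excitation-ratio features.

A standard sifting implementation: each intrinsic mode function (IMF) is
obtained by repeatedly subtracting the mean of the cubic-spline upper
and lower extrema envelopes until the stopping criterion is met.  IMFs
come out in decreasing order of oscillation frequency, so the top IMFs
capture high-frequency (turbulent-noise-like) content and the remainder
the harmonic signal; SNR/NSR-like ratios on plain energy, Teager-Kaiser
energy and amplitude entropy form the feature set.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import CubicSpline

from .noise_ratios import _entropy, _teager
from .registry import EMD_FEATURES

__all__ = ["emd", "emd_er_features"]

N_NOISE_IMFS = 2


def _envelope(x: np.ndarray, idx: np.ndarray, n: int) -> np.ndarray:
    # anchor endpoints to limit spline overshoot at the edges
    xs = np.concatenate([[0], idx, [n - 1]])
    ys = np.concatenate([[x[idx[0]]], x[idx], [x[idx[-1]]]])
    return CubicSpline(xs, ys)(np.arange(n))


def _extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d = np.diff(x)
    maxima = np.nonzero((d[:-1] > 0) & (d[1:] <= 0))[0] + 1
    minima = np.nonzero((d[:-1] < 0) & (d[1:] >= 0))[0] + 1
    return maxima, minima


def emd(
    x: np.ndarray,
    max_imfs: int = 6,
    max_siftings: int = 8,
    sd_threshold: float = 0.2,
) -> list[np.ndarray]:
    """Decompose ``x`` into IMFs (highest frequency first) plus residual.

    Returns the list of IMFs; the residual (trend) is not included.
    Raises ``ValueError`` if no oscillatory component can be extracted.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    residual = x.copy()
    imfs: list[np.ndarray] = []
    for _ in range(max_imfs):
        maxima, minima = _extrema(residual)
        if maxima.size < 3 or minima.size < 3:
            break
        h = residual
        for _ in range(max_siftings):
            maxima, minima = _extrema(h)
            if maxima.size < 3 or minima.size < 3:
                break
            mean_env = 0.5 * (_envelope(h, maxima, n) + _envelope(h, minima, n))
            h_new = h - mean_env
            denom = float(np.sum(h**2)) + 1e-30
            if float(np.sum((h - h_new) ** 2)) / denom < sd_threshold:
                h = h_new
                break
            h = h_new
        imfs.append(h)
        residual = residual - h
    if not imfs:
        raise ValueError("EMD failed: no oscillatory component found")
    return imfs


def emd_er_features(x: np.ndarray, fs: int) -> dict[str, float]:
    """IMF SNR/NSR ratios with the top (high-frequency) IMFs as noise."""
    imfs = emd(x)
    k = min(N_NOISE_IMFS, max(1, len(imfs) - 1))
    noise = np.sum(imfs[:k], axis=0)
    signal = np.sum(imfs[k:], axis=0) if len(imfs) > k else x - noise

    e_s = float(np.mean(signal**2)) + 1e-15
    e_n = float(np.mean(noise**2)) + 1e-15
    tk_s = float(np.mean(np.abs(_teager(signal)))) + 1e-15
    tk_n = float(np.mean(np.abs(_teager(noise)))) + 1e-15
    h_s = _entropy(signal) + 1e-12
    h_n = _entropy(noise) + 1e-12
    return dict(zip(EMD_FEATURES, [
        10.0 * np.log10(e_s / e_n),
        10.0 * np.log10(tk_s / tk_n),
        h_s / h_n,
        e_n / e_s,
        tk_n / tk_s,
        h_n / h_s,
    ]))
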