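"""Jitter and shimmer variant batteries and Glottal Quotient measures.

All variants are algorithmic variations of the same two concepts:
cycle-to-cycle perturbation of the vocal-fold period (jitter) and of the
cycle amplitude (shimmer).  Every normalized variant is invariant to
uniform amplitude scaling; shimmer variants are additionally invariant
to uniform time scaling (they depend only on amplitudes).
"""

from __future__ import annotations

import numpy as np

from .cycles import CycleSequence
from .registry import HNR_GQ_FEATURES, JITTER_FEATURES, SHIMMER_FEATURES

__all__ = ["jitter_family", "shimmer_family", "gq_features"]

_MIN_CYCLES = 3


def _mad(x: np.ndarray) -> float:
    """Mean absolute consecutive difference."""
    return float(np.mean(np.abs(np.diff(x))))


def _pq(x: np.ndarray, k: int) -> float:
    """Perturbation quotient: mean |x_i - moving_avg_k(x)_i| / mean(x).

    Centered window of k points; requires at least k cycles (else nan).
    """
    if x.size < k:
        return float("nan")
    kernel = np.ones(k) / k
    smooth = np.convolve(x, kernel, mode="valid")
    center = x[k // 2: k // 2 + smooth.size]
    return float(np.mean(np.abs(center - smooth)) / np.mean(x))


def _rmsd(x: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.diff(x) ** 2)))


def _p5p95(x: np.ndarray) -> float:
    return float(np.percentile(x, 95) - np.percentile(x, 5))


def _trim(x: np.ndarray) -> np.ndarray:
    """Middle 90% of values (5% trimmed at each end)."""
    lo, hi = np.percentile(x, [5, 95])
    mid = x[(x >= lo) & (x <= hi)]
    return mid if mid.size >= 2 else x


def _base_battery(x: np.ndarray) -> list[float]:
    """The ten-variant battery applied to a positive sequence."""
    m = float(np.mean(x))
    return [
        _mad(x) / m,
        _mad(x),
        _pq(x, 3),
        _pq(x, 5),
        _pq(x, 11),
        3.0 * _pq(x, 3),
        float(np.std(x)) / m,
        _p5p95(x) / m,
        _rmsd(x) / m,
        _mad(np.log(x)),
    ]


def jitter_family(cycles: CycleSequence) -> dict[str, float]:
    """Thirty jitter variants from the cycle-period sequence.

    Raises ``ValueError`` with an explanatory message when fewer than
    three cycles are available.
    """
    if cycles.n_cycles < _MIN_CYCLES:
        raise ValueError("jitter family requires at least 3 detected cycles")
    T = cycles.cycle_lengths
    F0 = cycles.f0_contour
    st = 12.0 * np.log2(F0 / np.median(F0))  # semitone contour
    trimmed = _trim(T)
    med = float(np.median(T))
    values = (
        _base_battery(T)
        + _base_battery(F0)
        + [
            _mad(st),
            float(np.std(st)),
            _rmsd(st),
            _p5p95(st),
            _pq(st - st.min() + 1.0, 5),  # shift to positive support for the quotient
        ]
        + [
            _mad(trimmed) / float(np.mean(trimmed)),
            float(np.std(trimmed)) / float(np.mean(trimmed)),
            float(np.max(np.abs(np.diff(T)))) / float(np.mean(T)),
            float(np.median(np.abs(np.diff(T)))) / med,
            float(np.mean(np.abs(T - med))) / med,
        ]
    )
    return dict(zip(JITTER_FEATURES, values))


def shimmer_family(cycles: CycleSequence) -> dict[str, float]:
    """Twenty-one shimmer variants from the cycle-amplitude sequence."""
    if cycles.n_cycles < _MIN_CYCLES:
        raise ValueError("shimmer family requires at least 3 detected cycles")
    A = cycles.cycle_amplitudes
    if np.any(A <= 0):
        A = np.clip(A, np.max(A) * 1e-6 if np.max(A) > 0 else 1e-12, None)
    E = A**2
    db = 20.0 * np.log10(A / np.median(A))
    trimmed = _trim(A)
    mA = float(np.mean(A))
    values = [
        _mad(A) / mA,
        float(np.mean(np.abs(np.diff(20.0 * np.log10(A))))),
        _pq(A, 3),
        _pq(A, 5),
        _pq(A, 11),
        3.0 * _pq(A, 3),
        float(np.std(A)) / mA,
        _p5p95(A) / mA,
        _rmsd(A) / mA,
        float(np.median(np.abs(np.diff(A)))) / float(np.median(A)),
        _mad(np.log(A)),
        _mad(E) / float(np.mean(E)),
        float(np.std(E)) / float(np.mean(E)),
        _pq(E, 5),
        _pq(E, 11),
        _mad(trimmed) / float(np.mean(trimmed)),
        float(np.std(trimmed)) / float(np.mean(trimmed)),
        float(np.max(np.abs(np.diff(A)))) / mA,
        float(np.std(db)),
        _p5p95(db),
        _rmsd(db),
    ]
    return dict(zip(SHIMMER_FEATURES, values))


def gq_features(phonation_samples: np.ndarray, fs: int, cycles: CycleSequence) -> dict[str, float]:
    """Glottal Quotient variants: variability of open/closed-phase durations.

    Within each detected cycle the "closed" (high-excitation) phase is
    approximated as the span where the smoothed rectified signal exceeds
    half its within-cycle maximum; the remainder of the cycle is "open".
    Perfectly regular cycles give zero variability.
    """
    if cycles.n_cycles < _MIN_CYCLES:
        raise ValueError("GQ requires at least 3 detected cycles")
    env = np.abs(phonation_samples)
    win = max(3, int(0.001 * fs))
    env = np.convolve(env, np.ones(win) / win, mode="same")
    onsets = cycles.cycle_onsets
    period_samples = cycles.cycle_lengths * fs
    closed = []
    for i, on in enumerate(onsets):
        end = on + int(round(period_samples[i]))
        seg = env[on:min(end, env.size)]
        if seg.size < 4:
            continue
        closed.append(float(np.sum(seg > 0.5 * seg.max())) / fs)
    closed_arr = np.asarray(closed)
    open_arr = cycles.cycle_lengths[:closed_arr.size] - closed_arr
    mean_T = float(np.mean(cycles.cycle_lengths))
    names = HNR_GQ_FEATURES[4:]
    return dict(zip(names, [
        _p5p95(closed_arr) / float(np.median(cycles.cycle_lengths)),
        float(np.std(open_arr)) / mean_T,
        float(np.std(closed_arr)) / mean_T,
    ]))
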