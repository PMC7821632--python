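"""Nonlinear dynamics measures: RPDE, DFA and PPE.

RPDE (recurrence period density entropy) measures the uncertainty of
vocal-fold cycle duration as the normalized entropy of the distribution
of close-return periods of the time-delay-embedded signal: an exactly
periodic signal returns after one fixed period (entropy ~ 0), an
aperiodic one spreads its return times.

DFA (detrended fluctuation analysis) estimates the scaling exponent of
self-similarity of the signal; uncorrelated noise gives an exponent near
0.5.  The registry feature is the exponent squashed into (0, 1) by the
logistic map; the raw exponent is exposed for direct checks.

PPE (pitch period entropy) is the entropy of the relative semitone pitch
sequence after removing the smooth (vibrato-like) trend, so that normal
slow F0 drift does not count as impairment.
"""

from __future__ import annotations

import numpy as np

from .cycles import CycleSequence

__all__ = ["rpde", "dfa_exponent", "dfa", "ppe"]


# ----------------------------------------------------------------- RPDE
def rpde(
    x: np.ndarray,
    fs: int,
    dim: int = 3,
    tau_s: float = 0.0005,
    radius_frac: float = 0.12,
    t_max_s: float = 0.02,
) -> float:
    """Recurrence period density entropy, normalized to [0, 1]."""
    x = np.asarray(x, dtype=float)
    sd = float(np.std(x))
    if sd == 0:
        raise ValueError("RPDE undefined for a constant signal")
    x = x / sd
    d = max(1, int(round(tau_s * fs)))
    n_emb = x.size - (dim - 1) * d
    t_max = int(round(t_max_s * fs))
    if n_emb <= t_max + 1:
        raise ValueError("signal too short for RPDE")
    emb = np.stack([x[i * d:i * d + n_emb] for i in range(dim)], axis=1)

    eps = radius_frac * np.sqrt(dim)
    n_base = n_emb - t_max
    base = emb[:n_base]
    exited = np.zeros(n_base, dtype=bool)
    returning = np.zeros(n_base, dtype=bool)
    done = np.zeros(n_base, dtype=bool)
    best_dist = np.full(n_base, np.inf)
    best_tau = np.zeros(n_base, dtype=int)
    counts = np.zeros(t_max + 1)
    # close returns: within each first re-entry episode into the eps-ball,
    # the recurrence period is the lag of minimum distance -- not the lag
    # of first entry, which is biased early by the ball radius
    for tau in range(1, t_max + 1):
        if done.all():
            break
        dist = np.linalg.norm(emb[tau:tau + n_base] - base, axis=1)
        inside = dist < eps
        active = exited & ~done
        entering = active & inside & ~returning
        returning |= entering
        improve = returning & ~done & (dist < best_dist)
        best_dist[improve] = dist[improve]
        best_tau[improve] = tau
        closing = returning & ~done & ~inside
        for t_rec in best_tau[closing]:
            counts[t_rec] += 1
        done |= closing
        exited |= ~inside
    still = returning & ~done
    for t_rec in best_tau[still]:
        counts[t_rec] += 1
    total = counts.sum()
    if total == 0:
        return 1.0
    p = counts[counts > 0] / total
    h = -np.sum(p * np.log(p))
    return max(0.0, float(h / np.log(t_max + 1)))


# ------------------------------------------------------------------ DFA
def dfa_exponent(x: np.ndarray, n_scales: int = 12) -> float:
    """Raw DFA scaling exponent (order-1 detrending)."""
    x = np.asarray(x, dtype=float)
    if np.std(x) == 0:
        raise ValueError("DFA undefined for a constant signal")
    y = np.cumsum(x - np.mean(x))
    n = y.size
    scales = np.unique(
        np.round(np.logspace(np.log10(10), np.log10(n // 8), n_scales)).astype(int)
    )
    flucts = []
    t_full = np.arange(n, dtype=float)
    for s in scales:
        n_win = n // s
        seg = y[: n_win * s].reshape(n_win, s)
        t = t_full[:s]
        t_mean = t.mean()
        t_var = float(np.sum((t - t_mean) ** 2))
        slope = (seg - seg.mean(axis=1, keepdims=True)) @ (t - t_mean) / t_var
        detr = seg - seg.mean(axis=1, keepdims=True) - slope[:, None] * (t - t_mean)
        flucts.append(np.sqrt(np.mean(detr**2)))
    coeffs = np.polyfit(np.log(scales), np.log(flucts), 1)
    return float(coeffs[0])


def dfa(x: np.ndarray) -> float:
    """DFA exponent squashed into (0, 1): 1 / (1 + exp(-alpha))."""
    alpha = dfa_exponent(x)
    return float(1.0 / (1.0 + np.exp(-alpha)))


# ------------------------------------------------------------------ PPE
def ppe(cycles: CycleSequence, n_bins: int = 30, span_semitones: float = 1.5) -> float:
    """Pitch period entropy of the detrended semitone F0 contour."""
    if not cycles.voiced or cycles.n_cycles < 5:
        raise ValueError("PPE requires a voiced F0 contour of >= 5 cycles")
    f0 = cycles.f0_contour
    st = 12.0 * np.log2(f0 / np.median(f0))
    # remove the smooth vibrato-like trend with a moving average (~10 cycles)
    win = min(11, st.size if st.size % 2 == 1 else st.size - 1)
    kernel = np.ones(win) / win
    trend = np.convolve(st, kernel, mode="same")
    resid = st - trend
    hist, _ = np.histogram(resid, bins=n_bins, range=(-span_semitones, span_semitones))
    total = hist.sum()
    if total == 0:
        return 0.0
    p = hist[hist > 0] / total
    h = -np.sum(p * np.log(p))
    return float(h / np.log(n_bins))
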