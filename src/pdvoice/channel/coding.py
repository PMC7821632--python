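"""Channel coding: rate-1/2 convolutional code with block interleaving.

A cellular voice link never sends codec bits uncoded over a severe-ISI
channel; the receiver's iterative (turbo) equalization is defined as the
joint loop between a soft equalizer and the decoder of a channel code.
This module provides the code half of that picture in its simplest
standard form: the ubiquitous constraint-length-7 rate-1/2 convolutional
code (generators 133/171 octal) with a block interleaver to break up the
error bursts a sequence detector produces on deep-notch channels, and
hard-decision Viterbi decoding.  The stage is pluggable and can be
disabled (``channel_coding="none"``) to study the uncoded link.
"""

from __future__ import annotations

import numpy as np

from .config import BitStream

__all__ = ["conv_encode", "conv_decode", "interleave", "deinterleave", "CODE_RATE"]

_G = (0o133, 0o171)       # generator polynomials, constraint length 7
_K = 7
_N_STATES = 1 << (_K - 1)
_FLUSH = _K - 1
CODE_RATE = 0.5
_INTERLEAVE_DEPTH = 32


def _parity(x: np.ndarray) -> np.ndarray:
    x = x.copy()
    for shift in (16, 8, 4, 2, 1):
        x ^= x >> shift
    return x & 1


def conv_encode(bits: np.ndarray) -> np.ndarray:
    """Encode bits (with ``K-1`` flush zeros appended) at rate 1/2."""
    bits = np.asarray(bits, dtype=np.int64).ravel()
    padded = np.concatenate([bits, np.zeros(_FLUSH, dtype=np.int64)])
    # register window: current bit in the low position
    reg = np.zeros(padded.size, dtype=np.int64)
    for k in range(_K):
        shifted = np.concatenate([np.zeros(k, dtype=np.int64), padded[:padded.size - k]])
        reg |= shifted << k
    out = np.empty(2 * padded.size, dtype=np.uint8)
    out[0::2] = _parity(reg & _G[0]).astype(np.uint8)
    out[1::2] = _parity(reg & _G[1]).astype(np.uint8)
    return out


def conv_decode(coded: np.ndarray, n_bits: int) -> np.ndarray:
    """Hard-decision Viterbi decoding back to ``n_bits`` information bits."""
    from .link import _viterbi_core  # shared add-compare-select core

    coded = np.asarray(coded, dtype=np.uint8).ravel()
    n_steps = n_bits + _FLUSH
    if coded.size < 2 * n_steps:
        raise ValueError("coded stream shorter than expected")
    r0 = coded[0:2 * n_steps:2].astype(np.float64)
    r1 = coded[1:2 * n_steps:2].astype(np.float64)

    # expected output pair for each (state, input bit); state = previous
    # K-1 input bits, most recent in the low bit
    s = np.arange(_N_STATES, dtype=np.int64)
    e = np.empty((2, _N_STATES * 2))
    for b in (0, 1):
        reg = (s << 1) | b
        e[0, s * 2 + b] = _parity(reg & _G[0])
        e[1, s * 2 + b] = _parity(reg & _G[1])
    bm = np.abs(r0[:, None] - e[0][None, :]) + np.abs(r1[:, None] - e[1][None, :])
    decoded = np.asarray(_viterbi_core(bm, _N_STATES), dtype=np.uint8)
    return decoded[:n_bits]


def interleave(values: np.ndarray, depth: int = _INTERLEAVE_DEPTH) -> np.ndarray:
    """Rectangular block interleaver (pads with zeros to a full block).

    Dtype-preserving: works on hard bits and on soft LLRs alike.
    """
    values = np.asarray(values).ravel()
    rows = int(np.ceil(values.size / depth))
    padded = np.concatenate([values, np.zeros(rows * depth - values.size, dtype=values.dtype)])
    return padded.reshape(rows, depth).T.ravel()


def deinterleave(values: np.ndarray, n_original: int, depth: int = _INTERLEAVE_DEPTH) -> np.ndarray:
    values = np.asarray(values).ravel()
    rows = int(np.ceil(n_original / depth))
    if values.size != rows * depth:
        raise ValueError("interleaved length mismatch")
    return values.reshape(depth, rows).T.ravel()[:n_original]


def protect(bits: BitStream) -> BitStream:
    """Encode + interleave a codec bit-stream for transmission."""
    coded = interleave(conv_encode(bits.bits))
    return BitStream(bits=coded, frame_length_bits=coded.size)


def unprotect(received: BitStream, n_bits: int, frame_length_bits: int) -> BitStream:
    """Deinterleave + decode back to the codec bit-stream."""
    n_coded = 2 * (n_bits + _FLUSH)
    coded = deinterleave(received.bits, n_coded)
    return BitStream(bits=conv_decode(coded, n_bits), frame_length_bits=frame_length_bits)
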