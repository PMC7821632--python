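"""Frame-based LPC speech codec with regular-pulse excitation.

A narrow-band (8 kHz) codec in the GSM full-rate mould, kept simple and
pluggable: per 20 ms frame, an order-10 LPC analysis is quantized as
6-bit log-area ratios, and the prediction residual is coded per 5 ms
subframe by regular-pulse excitation (decimation 3, 13 pulses of 3 bits,
a 2-bit grid offset and a 6-bit logarithmic block gain).  That is
248 bits per frame, ~12.4 kbit/s.  Quantized reflection coefficients
always stay inside the unit circle, so the synthesis filter remains
stable even when the bit-stream is corrupted by channel errors.

The codec interface (``encode_speech`` / ``decode_speech`` over a
:class:`BitStream`) is deliberately minimal so a bit-exact standard
codec could be swapped in without touching the rest of the chain.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import lfilter

from ..phonation import Phonation
from .config import BitStream, ChannelConfig

__all__ = ["encode_speech", "decode_speech", "bits_per_frame"]

_N_SUBFRAMES = 4
_DECIMATION = 3
_N_PULSES = 13
_LAR_BITS = 6
_LAR_RANGE = (-4.0, 4.0)
_GAIN_BITS = 6
_LOG2_GAIN_RANGE = (-16.0, 1.0)
_PULSE_BITS = 3
_GRID_BITS = 2


def bits_per_frame(lpc_order: int = 10) -> int:
    sub = _GRID_BITS + _GAIN_BITS + _N_PULSES * _PULSE_BITS
    return lpc_order * _LAR_BITS + _N_SUBFRAMES * sub


# ---------------------------------------------------------------- LPC math
def _levinson(r: np.ndarray, order: int) -> np.ndarray:
    """Reflection coefficients from an autocorrelation sequence."""
    a = np.zeros(order + 1)
    a[0] = 1.0
    err = r[0]
    ks = np.zeros(order)
    for i in range(1, order + 1):
        if err <= 0:
            break
        acc = r[i] + np.dot(a[1:i], r[i - 1:0:-1])
        k = -acc / err
        ks[i - 1] = k
        a[1:i + 1] = a[1:i + 1] + k * a[i - 1::-1][:i]
        err *= (1.0 - k * k)
    return ks


def _rc_to_lpc(ks: np.ndarray) -> np.ndarray:
    a = np.array([1.0])
    for k in ks:
        a = np.concatenate([a, [0.0]])
        a = a + k * a[::-1]
    return a


def _rc_to_lar(k: np.ndarray) -> np.ndarray:
    k = np.clip(k, -0.9999, 0.9999)
    return np.log((1.0 + k) / (1.0 - k))


def _lar_to_rc(lar: np.ndarray) -> np.ndarray:
    return np.tanh(lar / 2.0)


# ---------------------------------------------------------- quantizers
def _quantize_uniform(v: np.ndarray, lo: float, hi: float, bits: int) -> np.ndarray:
    levels = (1 << bits) - 1
    idx = np.round((np.clip(v, lo, hi) - lo) / (hi - lo) * levels)
    return idx.astype(np.int64)


def _dequantize_uniform(idx: np.ndarray, lo: float, hi: float, bits: int) -> np.ndarray:
    levels = (1 << bits) - 1
    return lo + np.asarray(idx, dtype=float) / levels * (hi - lo)


def _quantize_pulse(p: np.ndarray) -> np.ndarray:
    """3-bit midrise quantizer on [-1, 1]."""
    idx = np.floor((np.clip(p, -0.999, 0.999) + 1.0) * 4.0)
    return idx.astype(np.int64)


def _dequantize_pulse(idx: np.ndarray) -> np.ndarray:
    return (np.asarray(idx, dtype=float) + 0.5) / 4.0 - 1.0


def _pack(values: list[tuple[int, int]]) -> np.ndarray:
    """Pack (value, n_bits) pairs MSB-first into a 0/1 array."""
    out = []
    for v, nb in values:
        for b in range(nb - 1, -1, -1):
            out.append((v >> b) & 1)
    return np.asarray(out, dtype=np.uint8)


class _BitReader:
    def __init__(self, bits: np.ndarray):
        self.bits = bits
        self.pos = 0

    def read(self, nb: int) -> int:
        v = 0
        for _ in range(nb):
            v = (v << 1) | int(self.bits[self.pos])
            self.pos += 1
        return v


# ------------------------------------------------------------- encode
def encode_speech(phonation: Phonation, config: ChannelConfig) -> BitStream:
    """Encode a phonation (already at the codec rate) into a bit-stream."""
    if phonation.sample_rate != config.codec_rate_hz:
        raise ValueError(
            f"phonation must be resampled to codec rate {config.codec_rate_hz} Hz "
            f"(got {phonation.sample_rate})"
        )
    frame_n = config.frame_samples
    order = config.lpc_order
    if frame_n <= order:
        raise ValueError("codec frame shorter than the LPC order")
    if config.bits_per_frame is not None and config.bits_per_frame != bits_per_frame(order):
        raise ValueError(
            f"bits_per_frame={config.bits_per_frame} inconsistent with this codec's "
            f"frame size ({bits_per_frame(order)} bits at LPC order {order})"
        )
    x = phonation.samples
    n_frames = int(np.ceil(x.size / frame_n))
    x = np.pad(x, (0, n_frames * frame_n - x.size))
    sub_n = frame_n // _N_SUBFRAMES

    bits_chunks = []
    zi = np.zeros(order)
    for f in range(n_frames):
        frame = x[f * frame_n:(f + 1) * frame_n]
        # autocorrelation LPC with a light lag window for conditioning
        r = np.correlate(frame, frame, "full")[frame_n - 1:frame_n + order]
        r = r * np.exp(-0.5 * (2 * np.pi * 60.0 * np.arange(order + 1) / config.codec_rate_hz) ** 2)
        r[0] *= 1.0 + 1e-5
        ks = _levinson(r, order) if r[0] > 0 else np.zeros(order)
        lar_idx = _quantize_uniform(_rc_to_lar(ks), *_LAR_RANGE, _LAR_BITS)
        ks_q = _lar_to_rc(_dequantize_uniform(lar_idx, *_LAR_RANGE, _LAR_BITS))
        a_q = _rc_to_lpc(ks_q)

        resid, zi = lfilter(a_q, [1.0], frame, zi=zi)

        params: list[tuple[int, int]] = [(int(i), _LAR_BITS) for i in lar_idx]
        for s in range(_N_SUBFRAMES):
            seg = resid[s * sub_n:(s + 1) * sub_n]
            grids = [seg[g::_DECIMATION][:_N_PULSES] for g in range(_DECIMATION)]
            g_best = int(np.argmax([np.sum(g**2) for g in grids]))
            pulses = grids[g_best]
            gain = float(np.max(np.abs(pulses))) if pulses.size else 0.0
            log_gain = np.log2(gain) if gain > 0 else _LOG2_GAIN_RANGE[0]
            g_idx = int(_quantize_uniform(np.array([log_gain]), *_LOG2_GAIN_RANGE, _GAIN_BITS)[0])
            gain_q = float(2.0 ** _dequantize_uniform(np.array([g_idx]), *_LOG2_GAIN_RANGE, _GAIN_BITS)[0])
            p_idx = _quantize_pulse(pulses / gain_q)
            params.append((g_best, _GRID_BITS))
            params.append((g_idx, _GAIN_BITS))
            params.extend((int(i), _PULSE_BITS) for i in p_idx)
        bits_chunks.append(_pack(params))

    return BitStream(bits=np.concatenate(bits_chunks), frame_length_bits=bits_per_frame(order))


# ------------------------------------------------------------- decode
def decode_speech(bitstream: BitStream, config: ChannelConfig) -> Phonation:
    """Decode a bit-stream back into audio at the codec rate."""
    order = config.lpc_order
    if bitstream.frame_length_bits != bits_per_frame(order):
        raise ValueError("bit-stream frame length does not match codec configuration")
    frame_n = config.frame_samples
    sub_n = frame_n // _N_SUBFRAMES
    reader = _BitReader(bitstream.bits)
    out = np.zeros(bitstream.n_frames * frame_n)
    zi = np.zeros(order)
    for f in range(bitstream.n_frames):
        lar_idx = np.array([reader.read(_LAR_BITS) for _ in range(order)])
        ks_q = _lar_to_rc(_dequantize_uniform(lar_idx, *_LAR_RANGE, _LAR_BITS))
        a_q = _rc_to_lpc(ks_q)
        exc = np.zeros(frame_n)
        for s in range(_N_SUBFRAMES):
            g_best = reader.read(_GRID_BITS) % _DECIMATION
            g_idx = reader.read(_GAIN_BITS)
            gain_q = float(2.0 ** _dequantize_uniform(np.array([g_idx]), *_LOG2_GAIN_RANGE, _GAIN_BITS)[0])
            p_idx = np.array([reader.read(_PULSE_BITS) for _ in range(_N_PULSES)])
            pulses = _dequantize_pulse(p_idx) * gain_q
            pos = s * sub_n + g_best + _DECIMATION * np.arange(_N_PULSES)
            pos = pos[pos < (s + 1) * sub_n]
            exc[pos] = pulses[:pos.size]
        synth, zi = lfilter([1.0], a_q, exc, zi=zi)
        out[f * frame_n:(f + 1) * frame_n] = synth
    out = np.clip(out, -1.0, 1.0)
    return Phonation(samples=out, sample_rate=config.codec_rate_hz)
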