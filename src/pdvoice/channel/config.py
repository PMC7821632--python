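"""Configuration of the simulated voice-over-cellular chain.

``ChannelConfig`` holds every knob of the degradation pipeline: optional
pre-coding contamination, the narrow-band codec, the dispersive (ISI)
radio channel with additive white Gaussian noise, and the receiver's
equalizer.  The default ISI channel is the standard severe-ISI benchmark
("Proakis C") with taps [0.227, 0.460, 0.688, 0.460, 0.227] and a
moderate 10 dB channel SNR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ChannelConfig", "BitStream", "PROAKIS_C"]

PROAKIS_C = (0.227, 0.460, 0.688, 0.460, 0.227)


@dataclass(frozen=True)
class ChannelConfig:
    """All knobs of the degradation chain."""

    pre_noise: str = "none"                  # {"none", "awgn", "pink"}
    pre_noise_snr_db: float = 10.0
    codec_rate_hz: int = 8000
    codec_frame_ms: float = 20.0
    lpc_order: int = 10
    bits_per_frame: int | None = None        # None = codec's natural size
    channel_taps: tuple[float, ...] = PROAKIS_C
    channel_snr_db: float = 10.0
    equalizer: str = "mlse"                  # {"mlse", "mmse_linear", "none"}
    equalizer_length: int = 31
    channel_coding: str = "conv_r12"         # {"conv_r12", "none"}
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pre_noise not in ("none", "awgn", "pink"):
            raise ValueError("pre_noise must be none/awgn/pink")
        if self.equalizer not in ("mlse", "mmse_linear", "none"):
            raise ValueError("equalizer must be mlse/mmse_linear/none")
        if self.channel_coding not in ("conv_r12", "none"):
            raise ValueError("channel_coding must be conv_r12/none")
        taps = np.asarray(self.channel_taps, dtype=float)
        if taps.size == 0 or not np.all(np.isfinite(taps)):
            raise ValueError("channel_taps must be nonempty and finite")
        if self.codec_rate_hz <= 0 or self.codec_frame_ms <= 0 or self.lpc_order < 1:
            raise ValueError("invalid codec parameters")
        if not np.isfinite(self.pre_noise_snr_db):
            raise ValueError("pre_noise_snr_db must be finite")

    @property
    def frame_samples(self) -> int:
        return int(round(self.codec_rate_hz * self.codec_frame_ms / 1000.0))


@dataclass
class BitStream:
    """A frame-aligned binary sequence."""

    bits: np.ndarray            # uint8 in {0, 1}
    frame_length_bits: int

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        if np.any(self.bits > 1):
            raise ValueError("bits must be 0/1")
        if self.frame_length_bits <= 0 or self.bits.size % self.frame_length_bits:
            raise ValueError("bit count must be a multiple of frame_length_bits")

    @property
    def n_frames(self) -> int:
        return self.bits.size // self.frame_length_bits
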