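"""The full degradation chain: pre-noise -> resample -> codec -> channel.

``degrade`` reproduces what a sustained phonation recorded on wide-band
hardware would look like after travelling through a cellular voice call:
optional pre-coding contamination, polyphase anti-aliased resampling to
the 8 kHz codec rate, LPC coding to a bit-stream, transmission over the
dispersive noisy channel, equalization/detection, and decoding.  The
output stays at the codec rate; the final waveform is renormalized only
if it leaves [-1, 1].
"""

from __future__ import annotations

from dataclasses import replace
from math import gcd

import numpy as np
from scipy.signal import resample_poly

from ..phonation import Phonation
from .codec import decode_speech, encode_speech
from .config import ChannelConfig
from .link import bit_error_rate, equalize_detect, transmit
from .noise import add_noise

__all__ = ["degrade", "resample_to"]


def resample_to(phonation: Phonation, rate_hz: int) -> Phonation:
    if phonation.sample_rate == rate_hz:
        return phonation
    g = gcd(phonation.sample_rate, rate_hz)
    samples = resample_poly(phonation.samples, rate_hz // g, phonation.sample_rate // g)
    return phonation.with_samples(samples, rate_hz)


def degrade(phonation: Phonation, config: ChannelConfig) -> Phonation:
    """Run the full transmit/receive chain on one phonation.

    Deterministic given (input, config): all stage randomness derives
    from ``config.seed``.  Per-file transmission statistics (bit error
    rate, commanded SNRs) are recorded in the output metadata.
    """
    ph = phonation
    if config.pre_noise != "none":
        ph = add_noise(ph, config.pre_noise, config.pre_noise_snr_db, seed=config.seed)
    ph = resample_to(ph, config.codec_rate_hz)

    sent = encode_speech(ph, config)
    if config.channel_coding == "conv_r12":
        from .coding import protect
        from .turbo import turbo_receive

        tx = protect(sent)
        received = transmit(tx, config)
        recovered = turbo_receive(received, config, sent.bits.size,
                                  sent.frame_length_bits)
    else:
        received = transmit(sent, config)
        recovered = equalize_detect(
            received, config, sent.frame_length_bits, n_bits=sent.bits.size
        )
    decoded = decode_speech(recovered, config)

    samples = decoded.samples
    peak = float(np.max(np.abs(samples)))
    if peak > 1.0:
        samples = samples / peak

    out = replace(
        phonation,
        samples=samples,
        sample_rate=config.codec_rate_hz,
        meta=dict(phonation.meta),
    )
    out.meta["channel_ber"] = bit_error_rate(sent.bits, recovered.bits)
    out.meta["channel_snr_db"] = config.channel_snr_db
    out.meta["pre_noise"] = config.pre_noise
    return out
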