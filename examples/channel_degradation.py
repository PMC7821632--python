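"""Send one sustained vowel through the simulated cellular channel.

Synthesizes a healthy male /ah:/, transmits it through the full chain
(8 kHz LPC codec, severe-ISI channel at 10 dB, turbo-equalized receiver)
and reports what survives.
"""

import numpy as np

from pdvoice import ChannelConfig, default_voice_params, degrade, synthesize_phonation
from pdvoice.features import extract_cycles, preprocess

vowel = synthesize_phonation(default_voice_params("male", f0_mean=120.0), 24000, seed=1)
config = ChannelConfig(channel_snr_db=10.0, seed=7)   # Proakis C taps by default
received = degrade(vowel, config)

f0_in = np.mean(extract_cycles(preprocess(vowel)).f0_contour)
f0_out = np.mean(extract_cycles(preprocess(received)).f0_contour)

print(f"channel taps:        {config.channel_taps}")
print(f"channel SNR:         {config.channel_snr_db} dB")
print(f"bit error rate:      {received.meta['channel_ber']:.6f}")
print(f"output sample rate:  {received.sample_rate} Hz (codec rate)")
print(f"F0 before/after:     {f0_in:.1f} / {f0_out:.1f} Hz")
# With the turbo receiver the bit-stream is recovered error-free at
# 10 dB even on this hostile channel, so the remaining degradation is
# the 8 kHz bandwidth restriction and codec quantization -- F0 survives
# within a few percent, while fine perturbation measures are inflated.
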