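"""Channel chain: pre-noise, codec, link, equalization, full degrade."""

from __future__ import annotations

import numpy as np
import pytest

from pdvoice import (
    BitStream,
    ChannelConfig,
    Phonation,
    add_noise,
    decode_speech,
    default_voice_params,
    degrade,
    encode_speech,
    equalize_detect,
    resample_to,
    synthesize_phonation,
    transmit,
)
from pdvoice.channel import PROAKIS_C, detect_raw, pink_noise
from pdvoice.channel.coding import conv_decode, conv_encode, deinterleave, interleave
from pdvoice.features import extract_cycles, preprocess


class TestAddNoise:
    def test_awgn_snr_exact(self, typical_vowel):
        noisy = add_noise(typical_vowel, "awgn", 10.0, seed=1)
        noise = noisy.samples - typical_vowel.samples
        snr = 10 * np.log10(np.mean(typical_vowel.samples**2) / np.mean(noise**2))
        assert abs(snr - 10.0) < 0.1

    def test_vanishing_noise_limit(self, typical_vowel):
        noisy = add_noise(typical_vowel, "awgn", 60.0, seed=2)
        r = np.corrcoef(noisy.samples, typical_vowel.samples)[0, 1]
        assert r > 0.999

    def test_clean_component_untouched(self, typical_vowel):
        """Adding noise never alters the clean-signal component."""
        noisy = add_noise(typical_vowel, "pink", 5.0, seed=3)
        noise = noisy.samples - typical_vowel.samples
        # the residual is exactly the generated noise: re-adding it reproduces output
        np.testing.assert_allclose(typical_vowel.samples + noise, noisy.samples)

    def test_zero_power_rejected(self):
        silent = Phonation(np.zeros(24000), 24000)
        with pytest.raises(ValueError):
            add_noise(silent, "awgn", 10.0)

    def test_pink_noise_spectral_slope(self):
        """Pink noise falls ~3 dB/octave: log-log PSD slope -1 +/- 0.2."""
        from scipy.signal import welch

        rng = np.random.default_rng(4)
        x = pink_noise(2**17, rng)
        f, p = welch(x, fs=8000, nperseg=4096)
        band = (f >= 50) & (f <= 3000)
        slope = np.polyfit(np.log(f[band]), np.log(p[band]), 1)[0]
        assert slope == pytest.approx(-1.0, abs=0.2)


class TestCodec:
    def test_frame_arithmetic(self, default_channel):
        ph = Phonation(0.1 * np.sin(2 * np.pi * 200 * np.arange(24000) / 8000), 8000)
        bits = encode_speech(ph, default_channel)
        assert bits.n_frames == 150      # 3 s / 20 ms
        assert bits.bits.size == 150 * bits.frame_length_bits

    def test_silence_decodes_quietly(self, default_channel):
        silent = Phonation(np.zeros(8000), 8000)
        bits = encode_speech(silent, default_channel)
        out = decode_speech(bits, default_channel)
        energy_dbfs = 10 * np.log10(np.mean(out.samples**2) + 1e-30)
        assert energy_dbfs < -40.0

    def test_round_trip_preserves_f0(self, typical_vowel, default_channel):
        """Codec-only round trip (no channel): F0 within 2%."""
        ph8 = resample_to(typical_vowel, 8000)
        out = decode_speech(encode_speech(ph8, default_channel), default_channel)
        f0_in = np.mean(extract_cycles(preprocess(ph8)).f0_contour)
        f0_out = np.mean(extract_cycles(preprocess(out)).f0_contour)
        assert f0_out == pytest.approx(f0_in, rel=0.02)

    def test_round_trip_preserves_first_formant(self, typical_vowel, default_channel):
        """Spectral envelope: F1 peak location within one 31 Hz DFT bin."""
        from scipy.signal import welch

        ph8 = resample_to(typical_vowel, 8000)
        out = decode_speech(encode_speech(ph8, default_channel), default_channel)
        f, p_in = welch(ph8.samples, fs=8000, nperseg=256)
        _, p_out = welch(out.samples, fs=8000, nperseg=256)
        band = (f >= 400) & (f <= 1000)   # F1 region
        assert abs(f[band][np.argmax(p_in[band])] - f[band][np.argmax(p_out[band])]) <= f[1]

    def test_wrong_rate_rejected(self, typical_vowel, default_channel):
        with pytest.raises(ValueError):
            encode_speech(typical_vowel, default_channel)   # still 24 kHz

    def test_frame_shorter_than_lpc_order_rejected(self):
        cfg = ChannelConfig(codec_frame_ms=1.0, lpc_order=10)
        with pytest.raises(ValueError):
            encode_speech(Phonation(np.zeros(8000), 8000), cfg)


class TestLink:
    def test_identity_channel_recovers_bits(self):
        rng = np.random.default_rng(5)
        bits = BitStream(rng.integers(0, 2, 4000, dtype=np.uint8), 200)
        cfg = ChannelConfig(channel_taps=(1.0,), channel_snr_db=np.inf,
                            equalizer="mlse", seed=1)
        rx = transmit(bits, cfg)
        np.testing.assert_array_equal(rx[:4000], 2.0 * bits.bits - 1.0)
        rec = equalize_detect(rx, cfg, 200, n_bits=4000)
        np.testing.assert_array_equal(rec.bits, bits.bits)

    def test_convolution_length(self):
        bits = BitStream(np.ones(100, dtype=np.uint8), 100)
        rx = transmit(bits, ChannelConfig(seed=0))
        assert rx.size == 100 + len(PROAKIS_C) - 1

    def test_empty_bitstream_rejected(self):
        with pytest.raises(ValueError):
            transmit(BitStream(np.zeros(0, dtype=np.uint8), 1), ChannelConfig())

    def test_all_zero_received_gives_all_ones(self):
        cfg = ChannelConfig(equalizer="none")
        rec = equalize_detect(np.zeros(104), cfg, 100, n_bits=100)
        assert np.all(rec.bits == 1)

    def test_mismatched_length_rejected(self):
        with pytest.raises(ValueError):
            equalize_detect(np.zeros(10), ChannelConfig(), 100, n_bits=100)

    def test_ber_monotone_in_snr_and_equalizer_gain(self):
        """BER decreases with SNR; MMSE equalization beats raw detection."""
        rng = np.random.default_rng(6)
        bits = BitStream(rng.integers(0, 2, 20000, dtype=np.uint8), 1000)
        bers = {}
        for snr in (0, 10, 20):
            cfg = ChannelConfig(channel_snr_db=snr, equalizer="mmse_linear", seed=9)
            rec = equalize_detect(transmit(bits, cfg), cfg, 1000, n_bits=20000)
            bers[snr] = np.mean(rec.bits != bits.bits)
        assert bers[0] > bers[10] > bers[20]
        cfg = ChannelConfig(channel_snr_db=10, equalizer="mmse_linear", seed=9)
        rx = transmit(bits, cfg)
        ber_eq = np.mean(equalize_detect(rx, cfg, 1000, n_bits=20000).bits != bits.bits)
        ber_raw = np.mean(detect_raw(rx, 20000) != bits.bits)
        assert ber_eq < ber_raw


class TestCoding:
    def test_round_trip(self):
        rng = np.random.default_rng(8)
        bits = rng.integers(0, 2, 3000, dtype=np.uint8)
        np.testing.assert_array_equal(conv_decode(conv_encode(bits), bits.size), bits)

    def test_interleaver_inverse(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=777)
        np.testing.assert_array_equal(deinterleave(interleave(x), x.size), x)

    def test_corrects_sparse_errors(self):
        rng = np.random.default_rng(10)
        bits = rng.integers(0, 2, 3000, dtype=np.uint8)
        coded = conv_encode(bits)
        flip = rng.choice(coded.size, size=int(0.02 * coded.size), replace=False)
        coded[flip] ^= 1
        assert np.mean(conv_decode(coded, bits.size) != bits) < 0.005


class TestDegrade:
    def test_determinism(self, typical_vowel):
        cfg = ChannelConfig(seed=21)
        a = degrade(typical_vowel, cfg)
        b = degrade(typical_vowel, cfg)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_channel_free_limit_is_codec_round_trip(self, typical_vowel):
        cfg = ChannelConfig(channel_taps=(1.0,), channel_snr_db=np.inf,
                            channel_coding="none", seed=2)
        out = degrade(typical_vowel, cfg)
        ph8 = resample_to(typical_vowel, 8000)
        ref = decode_speech(encode_speech(ph8, cfg), cfg)
        np.testing.assert_allclose(out.samples, np.clip(ref.samples, -1, 1))
        assert out.meta["channel_ber"] == 0.0

    def test_output_in_unit_interval_and_at_codec_rate(self, typical_vowel, default_channel):
        out = degrade(typical_vowel, default_channel)
        assert out.sample_rate == 8000
        assert np.max(np.abs(out.samples)) <= 1.0

    def test_f0_survives_hostile_channel(self, typical_vowel, default_channel):
        """Proakis C at 10 dB with the turbo receiver: F0 within 5%."""
        out = degrade(typical_vowel, default_channel)
        f0_out = np.mean(extract_cycles(preprocess(out)).f0_contour)
        f0_in = np.mean(extract_cycles(preprocess(typical_vowel)).f0_contour)
        assert f0_out == pytest.approx(f0_in, rel=0.05)

    def test_pre_noise_applied(self, typical_vowel):
        cfg = ChannelConfig(pre_noise="awgn", pre_noise_snr_db=10.0, seed=3)
        out = degrade(typical_vowel, cfg)
        clean = degrade(typical_vowel, ChannelConfig(seed=3))
        assert not np.array_equal(out.samples, clean.samples)
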