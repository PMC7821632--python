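"""Dysphonia feature extraction: registry, families, invariances, oracles."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pdvoice import Phonation, default_voice_params, synthesize_phonation
from pdvoice.features import (
    FAMILIES,
    N_FEATURES,
    REGISTRY,
    CycleSequence,
    TooShortError,
    dfa_exponent,
    extract_all,
    extract_cycles,
    f0_family,
    gne_features,
    hnr_gq_family,
    jitter_family,
    mfcc_family,
    nonlinear_family,
    ppe,
    preprocess,
    rpde,
    shimmer_family,
    snr_band_family,
    vfer_features,
)
from pdvoice.features.emd import emd


def make_cycles(lengths_s, amplitudes, fs=24000):
    lengths = np.asarray(lengths_s, dtype=float)
    onsets = np.concatenate([[0], np.cumsum(np.round(lengths * fs))[:-1]]).astype(int)
    return CycleSequence(
        cycle_onsets=onsets,
        cycle_lengths=lengths,
        cycle_amplitudes=np.asarray(amplitudes, dtype=float),
        sample_rate=fs,
    )


class TestPreprocess:
    def test_middle_three_seconds(self):
        fs = 8000
        ph = Phonation(np.arange(5 * fs, dtype=float), fs)
        seg = preprocess(ph)
        assert seg.samples.size == 3 * fs
        # samples from t = 1.0 s to 4.0 s (up to the normalization gain)
        expected = np.arange(fs, 4 * fs, dtype=float)
        np.testing.assert_allclose(seg.samples, expected / expected.max())

    def test_exact_three_seconds_rescaled_only(self):
        fs = 8000
        rng = np.random.default_rng(0)
        x = 0.25 * rng.normal(size=3 * fs)
        seg = preprocess(Phonation(x, fs))
        np.testing.assert_allclose(seg.samples, x / np.max(np.abs(x)))

    def test_too_short_rejected(self):
        with pytest.raises(TooShortError):
            preprocess(Phonation(np.zeros(int(2.9 * 8000)), 8000))


class TestExtractCycles:
    def test_pulse_train_exact(self):
        fs = 8000
        x = np.zeros(4 * fs)
        x[::64] = 1.0   # 8 ms period = 125 Hz
        cyc = extract_cycles(preprocess(Phonation(x, fs)))
        assert cyc.voiced
        np.testing.assert_allclose(cyc.cycle_lengths, 0.008, atol=1e-9)
        np.testing.assert_allclose(cyc.f0_contour, 125.0, atol=1e-4)

    def test_synthesized_f0_within_5pct(self):
        ph = synthesize_phonation(default_voice_params("female", f0_mean=180.0), 24000, seed=8)
        cyc = extract_cycles(preprocess(ph))
        assert np.mean(cyc.f0_contour) == pytest.approx(180.0, rel=0.05)

    def test_white_noise_flagged_unvoiced(self, white_noise_phonation):
        cyc = extract_cycles(preprocess(white_noise_phonation))
        assert not cyc.voiced and cyc.flag == "unvoiced"
        assert cyc.n_cycles == 0

    def test_coverage_on_synthetic_vowel(self, typical_vowel):
        seg = preprocess(typical_vowel)
        cyc = extract_cycles(seg)
        span = (cyc.cycle_onsets[-1] - cyc.cycle_onsets[0]) / seg.samples.size
        assert span >= 0.90
        assert np.all((cyc.f0_contour >= 50) & (cyc.f0_contour <= 500))


class TestJitterShimmerOracles:
    def test_local_jitter_hand_value(self):
        cyc = make_cycles([0.010, 0.011, 0.010, 0.011], [1, 1, 1, 1])
        values = jitter_family(cyc)
        assert values["jitter_T_mad_rel"] == pytest.approx(0.001 / 0.0105, rel=1e-9)

    def test_local_shimmer_hand_value(self):
        cyc = make_cycles([0.01] * 4, [1.0, 1.1, 1.0, 1.1])
        values = shimmer_family(cyc)
        assert values["shimmer_A_mad_rel"] == pytest.approx(0.1 / 1.05, rel=1e-9)

    def test_constant_cycles_all_zero(self):
        cyc = make_cycles([0.008] * 20, [0.5] * 20)
        assert all(v == pytest.approx(0.0, abs=1e-12) for v in jitter_family(cyc).values())
        assert all(v == pytest.approx(0.0, abs=1e-12) for v in shimmer_family(cyc).values())

    def test_amplitude_scaling_invariance(self):
        rng = np.random.default_rng(1)
        lengths = 0.008 * (1 + 0.01 * rng.normal(size=40))
        amps = 1 + 0.05 * rng.normal(size=40)
        a = make_cycles(lengths, amps)
        b = make_cycles(lengths, 2.0 * amps)
        for k, v in jitter_family(a).items():
            assert jitter_family(b)[k] == pytest.approx(v, rel=1e-9), k
        for k, v in shimmer_family(a).items():
            assert shimmer_family(b)[k] == pytest.approx(v, rel=1e-9), k

    def test_shimmer_independent_of_periods(self):
        rng = np.random.default_rng(2)
        amps = 1 + 0.05 * rng.normal(size=30)
        a = make_cycles([0.008] * 30, amps)
        b = make_cycles([0.016] * 30, amps)   # time-dilated
        for k, v in shimmer_family(a).items():
            assert shimmer_family(b)[k] == pytest.approx(v, rel=1e-9), k

    def test_too_few_cycles_raise(self):
        cyc = make_cycles([0.01, 0.01], [1, 1])
        with pytest.raises(ValueError):
            jitter_family(cyc)
        with pytest.raises(ValueError):
            shimmer_family(cyc)

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_local_formulas_match_brute_force(self, seed):
        """Local jitter/shimmer equal an index-by-index loop to 1e-12."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 60))
        T = 0.008 * (1 + 0.02 * rng.normal(size=n))
        A = np.abs(1 + 0.1 * rng.normal(size=n)) + 0.01
        cyc = make_cycles(T, A)
        jit = jitter_family(cyc)["jitter_T_mad_rel"]
        shim = shimmer_family(cyc)["shimmer_A_mad_rel"]
        jit_bf = sum(abs(T[i] - T[i - 1]) for i in range(1, n)) / (n - 1) / (sum(T) / n)
        shim_bf = sum(abs(A[i] - A[i - 1]) for i in range(1, n)) / (n - 1) / (sum(A) / n)
        assert jit == pytest.approx(jit_bf, rel=1e-12)
        assert shim == pytest.approx(shim_bf, rel=1e-12)


class TestHNRGQ:
    def test_noiseless_vowel_high_hnr(self, noiseless_vowel):
        seg = preprocess(noiseless_vowel)
        cyc = extract_cycles(seg)
        values = hnr_gq_family(seg, cyc)
        assert values["hnr_mean_db"] > 30.0

    def test_aspiration_lowers_hnr(self, noiseless_params):
        noisy = replace(noiseless_params, aspiration_snr_db=10.0)
        ph_n = synthesize_phonation(noisy, 24000, seed=4)
        ph_c = synthesize_phonation(noiseless_params, 24000, seed=4)
        h = {}
        for tag, ph in (("clean", ph_c), ("noisy", ph_n)):
            seg = preprocess(ph)
            h[tag] = hnr_gq_family(seg, extract_cycles(seg))["hnr_mean_db"]
        assert h["noisy"] < h["clean"]

    def test_gq_zero_on_regular_cycles(self):
        fs = 8000
        x = np.zeros(4 * fs)
        x[::80] = 1.0
        seg = preprocess(Phonation(x, fs))
        values = hnr_gq_family(seg, extract_cycles(seg))
        assert values["gq_std_open_rel"] == pytest.approx(0.0, abs=1e-9)
        assert values["gq_std_closed_rel"] == pytest.approx(0.0, abs=1e-9)


class TestNonlinear:
    def test_rpde_near_zero_on_periodic(self):
        fs = 8000
        t = np.arange(4 * fs) / fs
        x = np.sin(2 * np.pi * 125 * t)    # exact 64-sample period
        assert rpde(x[: 2 * fs], fs) < 0.05

    def test_rpde_high_on_noise(self):
        rng = np.random.default_rng(3)
        assert rpde(rng.normal(size=16000), 8000) > 0.5

    def test_dfa_white_noise_half(self):
        """Uncorrelated noise has DFA exponent 0.5 (Monte-Carlo, n=50)."""
        rng = np.random.default_rng(11)
        alphas = [dfa_exponent(rng.normal(size=8000)) for _ in range(50)]
        assert np.mean(alphas) == pytest.approx(0.5, abs=0.05)

    def test_ppe_minimal_for_constant_f0(self):
        const = make_cycles([0.008] * 50, [1.0] * 50)
        rng = np.random.default_rng(7)
        varied = make_cycles(0.008 * (1 + 0.04 * rng.normal(size=50)), [1.0] * 50)
        assert ppe(const) == pytest.approx(0.0, abs=1e-9)
        assert ppe(varied) > ppe(const)

    def test_degenerate_signal_rejected(self):
        with pytest.raises(ValueError):
            rpde(np.ones(8000), 8000)
        with pytest.raises(ValueError):
            dfa_exponent(np.zeros(4000))


class TestBandFamilies:
    def test_band_limited_signal_at_snr_ceiling(self):
        fs = 8000
        t = np.arange(3 * fs) / fs
        x = sum(np.sin(2 * np.pi * f * t) for f in (200, 400, 800, 1600))
        values = vfer_features(x, fs)
        assert values["vfer_nsr_seo"] < 1e-3          # noise band nearly empty
        assert values["vfer_snr_seo"] > 30.0          # dB ceiling

    def test_highpass_noise_lowers_vfer_snr(self):
        fs = 8000
        rng = np.random.default_rng(5)
        t = np.arange(3 * fs) / fs
        x = sum(np.sin(2 * np.pi * f * t) for f in (200, 400, 800))
        spec = np.fft.rfft(rng.normal(size=x.size))
        freqs = np.fft.rfftfreq(x.size, 1 / fs)
        hp = np.fft.irfft(spec * (freqs > 2500), x.size)
        noisy = x + 2.0 * hp
        assert vfer_features(noisy, fs)["vfer_snr_seo"] < vfer_features(x, fs)["vfer_snr_seo"]

    def test_gne_high_for_harmonic_low_for_noise(self):
        fs = 8000
        t = np.arange(3 * fs) / fs
        pulse = np.zeros(t.size)
        pulse[::64] = 1.0
        rng = np.random.default_rng(6)
        g_harm = gne_features(pulse, fs)["gne_mean"]
        g_noise = gne_features(rng.normal(size=t.size), fs)["gne_mean"]
        assert g_harm > g_noise

    def test_emd_pure_tone_noise_fraction_small(self):
        """First (high-frequency) IMFs of a low-frequency tone carry <5% energy."""
        fs = 8000
        t = np.arange(2 * fs) / fs
        x = np.sin(2 * np.pi * 100 * t)
        imfs = emd(x)
        assert len(imfs) >= 1
        total = np.sum(x**2)
        top = np.sum(np.sum(np.asarray(imfs[:-1]) ** 2, axis=1)) if len(imfs) > 1 else 0.0
        assert top / total < 0.05


class TestMFCC:
    def test_gain_shifts_log_energy_only(self, typical_vowel):
        seg = preprocess(typical_vowel).samples
        a = mfcc_family(seg, 24000)
        b = mfcc_family(2.0 * seg, 24000)
        assert b["log_energy_mean"] - a["log_energy_mean"] == pytest.approx(np.log(4.0), abs=1e-9)
        for i in range(1, 13):
            assert b[f"mfcc_{i}_mean"] == pytest.approx(a[f"mfcc_{i}_mean"], abs=1e-9)

    def test_registry_count(self):
        assert len(FAMILIES["mfcc"]) == 42

    def test_stationary_signal_has_small_deltas(self):
        fs = 8000
        t = np.arange(3 * fs) / fs
        x = np.sin(2 * np.pi * 220 * t)
        values = mfcc_family(x, fs)
        static_scale = np.mean([abs(values[f"mfcc_{i}_mean"]) for i in range(1, 13)])
        delta_scale = np.mean([abs(values[f"mfcc_{i}_delta"]) for i in range(1, 13)])
        assert delta_scale < 0.01 * static_scale


class TestF0Family:
    def test_constant_contour(self):
        cyc = make_cycles([1.0 / 120.0] * 20, [1.0] * 20)
        values = f0_family(cyc, "male", norms={"male": 120.0, "female": 210.0})
        assert values["f0_mean"] == pytest.approx(120.0)
        assert values["f0_median"] == pytest.approx(120.0)
        assert values["f0_std"] == pytest.approx(0.0, abs=1e-9)
        assert values["f0_norm_dev_abs"] == pytest.approx(0.0, abs=1e-9)

    def test_relative_deviation(self):
        cyc = make_cycles([1.0 / 132.0] * 20, [1.0] * 20)
        values = f0_family(cyc, "male", norms={"male": 120.0, "female": 210.0})
        assert values["f0_norm_dev_rel"] == pytest.approx(0.10, rel=1e-6)


class TestExtractAll:
    def test_vector_length_and_families(self, typical_vowel):
        fv = extract_all(typical_vowel, sex="male")
        assert len(fv) == N_FEATURES == 132
        assert list(fv.values.keys()) == REGISTRY
        assert len(fv.family("jitter")) == 30
        assert len(fv.family("shimmer")) == 21
        assert len(fv.family("f0")) == 8

    def test_determinism(self, typical_vowel):
        a = extract_all(typical_vowel, sex="male").as_series()
        b = extract_all(typical_vowel, sex="male").as_series()
        np.testing.assert_array_equal(a.to_numpy(), b.to_numpy())

    def test_unvoiced_input_missing_with_reasons(self, white_noise_phonation):
        fv = extract_all(white_noise_phonation, sex="male")
        assert len(fv) == 132
        assert np.isnan(fv.values["jitter_T_mad_rel"])
        assert "jitter_T_mad_rel" in fv.missing
        # spectral measures remain computable on unvoiced input
        assert np.isfinite(fv.values["mfcc_1_mean"])

    def test_commanded_jitter_increases_measured_jitter(self, noiseless_params):
        measured = []
        for j in (0.005, 0.02, 0.05):
            ph = synthesize_phonation(replace(noiseless_params, jitter_frac=j), 24000, seed=6)
            measured.append(extract_all(ph, sex="male").values["jitter_T_mad_rel"])
        assert measured[0] < measured[1] < measured[2]

    def test_aspiration_decreases_hnr_and_vfer(self, noiseless_params):
        hnr, vfer = [], []
        for snr in (np.inf, 20.0, 10.0):
            ph = synthesize_phonation(replace(noiseless_params, aspiration_snr_db=snr), 24000, seed=9)
            fv = extract_all(ph, sex="male")
            hnr.append(fv.values["hnr_mean_db"])
            vfer.append(fv.values["vfer_snr_seo"])
        assert hnr[0] > hnr[1] > hnr[2]
        assert vfer[0] > vfer[1] > vfer[2]
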