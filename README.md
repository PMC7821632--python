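# pdvoice

Estimating Parkinson's disease symptom severity from sustained-vowel
phonations transmitted over a noisy cellular voice channel.

## The problem

People with Parkinson's are typically assessed in clinic every 6–12
months on the Unified Parkinson's Disease Rating Scale (UPDRS;
motor part 0–108, total 0–176, higher = more severe). Speech degrades
measurably with PD, and sustained vowel phonations (/ah:/) recorded at
home can replicate UPDRS to within a few points — but dedicated
recording hardware is expensive. The question this package addresses:
**does enough acoustic information survive an ordinary mobile-phone
voice call to keep UPDRS estimation clinically useful?** (Clinically
useful means a mean absolute error below the 4–5 point inter-rater
variability of human raters.)

`pdvoice` implements the full analysis as a tested, reusable pipeline:

1. **synthetic cohort** (`pdvoice.cohort`) — subjects with near-linear
   UPDRS trajectories assessed at weeks 0/13/26, weekly sessions of six
   phonations (four comfortable, two at twice the loudness), and a
   source-filter vowel synthesizer whose degradation parameters (jitter,
   shimmer, aspiration noise, F0 wander, loudness) are a known monotone
   function of severity — so every downstream stage is testable without
   any clinical data;
2. **channel simulation** (`pdvoice.channel`) — pre-coding contamination
   (AWGN/pink), polyphase resampling to 8 kHz, a GSM-flavoured
   regular-pulse-excitation LPC codec (~12.4 kbit/s), antipodal
   modulation over a severe-ISI channel (Proakis C taps
   `[0.227, 0.460, 0.688, 0.460, 0.227]`) with additive noise at a
   moderate 10 dB SNR, and a receiver (turbo equalization of the coded
   stream; MLSE / linear MMSE for the uncoded link);
3. **feature extraction** (`pdvoice.features`) — 132 dysphonia measures
   from the middle 3 s of each phonation: 30 jitter and 21 shimmer
   variants, HNR/NHR and Glottal Quotient, RPDE, DFA, PPE, GNE, VFER and
   EMD excitation ratios, 42 MFCC summaries, 8 F0 statistics;
4. **feature selection** (`pdvoice.select`) — LASSO, mRMR, ReliefF and
   random-forest permutation importance, aggregated by perturbation
   voting, subset size fixed by the one-standard-error rule;
5. **mapping & validation** (`pdvoice.mapping`) — random-forest
   multi-class mapping of features to integer UPDRS, evaluated by
   10-fold cross-validation repeated 100 times and by a
   leave-one-subject-out *tracking* scheme where the left-out subject's
   first four weeks (with their known UPDRS) calibrate the model.

Accuracy is reported as the mean absolute error
`MAE = (1/N) Σ_{i∈Q} |ŷᵢ − yᵢ|` with its standard deviation and
empirical 95% confidence interval over repeats.

## Worked example

```python
from pdvoice import ChannelConfig, default_voice_params, degrade, synthesize_phonation
from pdvoice.features import extract_all

vowel = synthesize_phonation(default_voice_params("male", f0_mean=120.0), 24000, seed=1)
received = degrade(vowel, ChannelConfig(channel_snr_db=10.0, seed=7))
print(received.meta["channel_ber"])            # 0.0  (turbo receiver at 10 dB)
clean, noisy = extract_all(vowel, "male"), extract_all(received, "male")
print(round(clean.values["f0_mean"], 1), round(noisy.values["f0_mean"], 1))
# 120.2 120.9   <- F0 survives the call
print(round(clean.values["hnr_mean_db"], 1), round(noisy.values["hnr_mean_db"], 1))
# 24.0 8.4      <- harmonicity is heavily degraded by the 8 kHz codec
```

End-to-end on a synthetic cohort (`python examples/validate_pipeline.py`,
about two minutes): a ten-subject male cohort through the 10 dB channel
gives a cross-validated MAE of 4.35 ± 0.28 motor-UPDRS points versus
7.16 for the dummy (train-mean) baseline — a 39% improvement, so the
severity information survives the call (the larger 42-subject run in
`scripts/acceptance.py` reaches ≈ 3.1 versus 6.6). The `examples/` scripts walk through each stage
(`synthesize_cohort.py`, `channel_degradation.py`, `extract_features.py`,
`feature_selection.py`, `validate_pipeline.py`), and the `pdvoice` CLI
(`synthesize`, `degrade`, `extract`, `select`, `validate`) exposes the
same stages from a shell.

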