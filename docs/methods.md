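# Methods

This note documents the models, parameter choices and numerical
decisions behind `pdvoice`, and what the synthetic experiments do and do
not demonstrate.

## Synthetic cohort

The generator emulates a six-month home-monitoring trial of early,
unmedicated PD: 28 male and 14 female subjects by default, clinical
UPDRS assessments at weeks 0, 13 and 26, and one weekly session of six
sustained /ah:/ phonations (slots 1–4 at comfortable loudness, slots 5–6
at twice the comfortable loudness, realized as a ×2 amplitude gain).

**Clinical trajectories.** Baseline motor-UPDRS is drawn per sex from
the published cohort statistics of the trial being emulated
(male 20.3 ± 8.5, female 17.6 ± 7.4; total-UPDRS adds an extra
component so total ≥ motor), and progresses linearly at a per-subject
rate (mean slope matching the reported three/six-month group means,
≈ 0.07–0.10 points/week) plus week-to-week Gaussian wobble
(sd 0.5 points). Early-stage progression is treated as linear, which is
the same assumption the analysis side uses when interpolating sparse
assessments; trajectories are clipped to the scale ranges.

**Voice synthesis.** A source-filter model: a Rosenberg glottal pulse
train (open phase 40%, return 16% of the nominal cycle) drives a cascade
of three second-order formant resonators (defaults ~700/1220/2600 Hz for
/ah:/, female formants shifted +12%; F2 stays below the ~1.7 kHz bound
appropriate for this vowel). Cycle onsets live on a continuous time
axis and the pulse is evaluated at the exact phase of each output
sample, so commanded cycle lengths are realized without sample-grid
quantization. The pulse *shape* is fixed (tied to the nominal period,
not the local one): perturbing onsets then moves every waveform landmark
one-for-one with the commanded period, making commanded jitter the
quantity a cycle tracker should recover. Period and amplitude
perturbations are zero-mean Gaussians scaled so that the expected
cycle-to-cycle |difference| equals the commanded `jitter_frac` /
`shimmer_frac` (σ = commanded × √π/2); F0 wander is an AR(1) drift with
the commanded stationary sd; aspiration noise is white Gaussian mixed
into the source at `aspiration_snr_db` and shaped by the same formant
filter. Output is scaled to peak 0.35 at unit loudness so the ×2 loud
condition stays inside [−1, 1].

**Severity link.** Each degradation parameter is linear in motor-UPDRS
with sex-specific slopes scaled by `link_strength` (default 1): per
UPDRS point, jitter +2.5e−4 (male) / +2.0e−4 (female), shimmer +8e−4 /
+6.5e−4, F0 wander +1.5e−4 / +1.8e−4, aspiration SNR −0.15 / −0.12 dB,
loudness −0.3% / −0.4%. A seeded multiplicative factor (uniform
0.8–1.2, constant across the sweep for a fixed seed) models
between-subject variation while keeping the map exactly monotone. The
link is a *testing device* — it encodes the monotone
acoustics-to-severity association the analysis exploits; it is not a
physiological model of how UPDRS maps to voice, which no published
acoustic model provides. Consequences: synthetic cohorts are *easier*
than real data (the association is noiseless apart from the synthesis
and channel), so passing end-to-end tests demonstrates that the pipeline
recovers severity information that is present, not that real phonations
carry this much information. Real-data phenomena not emulated include
vocal fry, diplophonia, session-level recording variation, microphone
transfer functions, coughs and aborted phonations.

## Channel simulation

The chain is pre-noise → resample → encode → transmit → receive →
decode, every stage seeded from the config.

* **Pre-coding contamination**: AWGN or pink noise (1/f power spectrum,
  synthesized in the frequency domain) scaled against the *measured*
  clean-signal power, so the empirical SNR equals the commanded SNR by
  construction; the clean component is never altered.
* **Codec**: a frame-based LPC codec in the GSM full-rate mould — 8 kHz,
  20 ms frames, order-10 autocorrelation LPC quantized as 6-bit
  log-area ratios, residual coded per 5 ms subframe by regular-pulse
  excitation (decimation 3, 13 pulses × 3 bits, 2-bit grid, 6-bit log
  gain): 248 bits/frame ≈ 12.4 kbit/s. Quantized reflection
  coefficients stay inside the unit circle, so the synthesis filter is
  stable even on corrupted bit-streams. The codec interface is
  pluggable; a bit-exact standard codec could be swapped in.
* **Link**: antipodal (BPSK-equivalent) symbols convolved with the
  channel taps plus white Gaussian noise at `channel_snr_db` relative to
  the noiseless received power. The default taps are the standard
  severe-ISI benchmark `[0.227, 0.460, 0.688, 0.460, 0.227]` at 10 dB —
  a deliberately hostile setting with a near-null in the channel
  spectrum.
* **Receiver.** Three detectors are implemented. A linear MMSE FIR
  equalizer (31 taps, MMSE-optimal delay) is the textbook baseline, but
  on this channel its measured bit-error rate at 10 dB is ≈ 0.17 — at
  that rate every codec frame is corrupted and the decoded audio carries
  no severity information, which is *not* the regime the underlying
  study operates in (its receiver performs iterative, turbo-style
  equalization). The package therefore also provides MLSE (Viterbi over
  the 2^(L−1)-state ISI trellis; BER ≈ 0.077 at 10 dB uncoded) and, as
  the chain default, channel coding with turbo equalization: a rate-1/2
  constraint-length-7 convolutional code (generators 133/171) with a
  depth-32 block interleaver, received by iterating a max-log BCJR
  equalizer against a max-log BCJR decoder (up to 4 iterations, early
  stop on convergence). Measured BER at 10 dB on the benchmark channel:
  0 over 10⁵ bits — matching the published behavior of turbo
  equalization on exactly this channel. The audible degradation of the
  default chain is therefore the 8 kHz bandwidth restriction plus codec
  quantization, with the channel kept honest by the coded link. The
  uncoded detectors remain available (`channel_coding="none"`,
  `equalizer="mmse_linear"|"mlse"|"none"`) and are what the bit-error
  property tests exercise.
* Decoded audio is renormalized only if it leaves [−1, 1].

## Feature extraction (132 measures)

Preprocessing takes the middle 3 s of the phonation and normalizes to
unit peak amplitude (the normalization choice is recorded in metadata).
Note that peak normalization removes absolute loudness, so severity
information enters through perturbation, noise and spectral measures
rather than energy level.

**Cycle tracker.** Framewise normalized autocorrelation (40 ms frames,
10 ms hop) with unbiased lag normalization, parabolic peak
interpolation, a subharmonic guard (among autocorrelation peaks within
10% of the maximum, the smallest lag wins) and a voicing threshold of
0.45 gives the coarse F0 (bounds 50–500 Hz) and the voicing decision
(< 50% voiced frames ⇒ flagged unvoiced). Cycle marks are then placed
on the smoothed rectified linear-prediction residual — inverse filtering
removes the vocal-tract resonances, leaving glottal-closure spikes whose
spacing measures each period to sub-sample accuracy, where raw waveform
peak spacing systematically understates perturbation because formant
ringing smears the landmarks. Marks are selected by height-greedy
peak-picking with a ¾-period minimum spacing, refined by correlating the
cycle-averaged excitation template around each mark (averaging
suppresses aspiration and channel noise), boundary cycles are dropped,
and cycles outside 0.6–1.5× the median period are excluded. On
noiseless synthesis the commanded jitter is recovered within ~15%
relative over the 0.002–0.05 range; under heavy aspiration noise
measured jitter is inflated (as with any tracker) but remains monotone
in the commanded value.

**Families** (names and order fixed by a versioned registry, 132 total):
jitter 30 (mean-absolute-difference, RAP/PPQ-style quotients, sd, range,
RMS-difference and log variants on periods, the F0 contour and the
semitone contour, plus trimmed variants); shimmer 21 (the same ideas on
cycle amplitudes, dB variants, energy variants); HNR/NHR 4 (from the
framewise normalized autocorrelation, HNR = 10 log₁₀(r/(1−r)));
GQ 3 (variability of open/closed-phase durations, the closed phase
approximated as the span where the smoothed rectified signal exceeds
half its within-cycle maximum); RPDE 1 (normalized entropy of
close-return periods of the time-delay-embedded signal, with the return
period taken at the distance minimum within each return episode — the
first-entry convention is biased early by the ball radius and does not
vanish on exact periodicity); DFA 1 (order-1 detrended fluctuation
exponent squashed to (0,1) by the logistic map; the raw exponent is
exposed and equals 0.5 on white noise); PPE 1 (normalized entropy of the
semitone F0 contour after removing a moving-average vibrato trend);
GNE 6 (maximum Hilbert-envelope correlations between non-adjacent
500 Hz bands, plus SNR/NSR variants on the band-envelope split); VFER 9
(energy, Teager energy and entropy ratios across the 2.5 kHz
signal/noise split); EMD-ER 6 (the same ratio concepts with the top two
intrinsic mode functions of an in-package sifting EMD as the noise
part); MFCC 42 (log energy + cepstra 0–12, 25 ms/10 ms frames, 26 mel
filters, DCT-II, means of static/Δ/ΔΔ over frames); F0 8 (mean, median,
sd, min, max, range, absolute and relative deviation from a
configurable sex-specific norm, defaults 120/210 Hz).

Band-based and recurrence measures (GNE, VFER, EMD-ER, RPDE) are
evaluated at a fixed 8 kHz analysis rate (the telephone output rate;
inputs at other rates are resampled internally), so the 2.5 kHz split
means the same thing for clean wide-band and channel-degraded
recordings — the "noise" band is then 2.5–4 kHz. Features that cannot
be computed (unvoiced input, decomposition failure) are carried as NaN
with a reason and imputed by training-fold medians at modelling time,
never at extraction time.

## Feature selection

LASSO ranks by order of entry along the L1 path (integer response,
regression view); mRMR uses mutual information on 10-bin equal-frequency
discretizations with the relevance-minus-redundancy criterion; ReliefF
uses k = 10 neighbours per class over all instances with prior-weighted
miss contributions; RF importance is out-of-bag permutation importance
over an explicit bagging loop (500 trees by default). Rankings operate
on a canonical (sorted) column order and break ties by name, so they are
invariant to input column layout. Voting runs each ranker on 10
subsampled datasets (90% without replacement); each run votes for its
top 30; the aggregate sorts by votes, then mean rank, then name. The
subset size K is the smallest K whose cross-validated mean MAE is within
one sd (at the argmin) of the global minimum; by construction K never
exceeds the argmin.

## Mapping and validation

Weekly responses come from piecewise-linear interpolation through the
measured assessments, rounded to the nearest integer (ties .5 away from
zero) to give a multi-class problem. The learner is a random forest
(500 trees, √M features per split, no class weighting); the predicted
score is the predicted class label. Subject identifiers, age, sex,
timing and loudness columns are stripped and asserted absent before
every fit.

Cross-validation permutes rows and splits into contiguous blocks per
repeat (10 folds; nominal sizes n_test = ⌊N/10⌋, n_train = N − n_test,
so 4010 → 3609/401 and 1865 → 1679/186); the per-repeat MAE is the mean
over fold MAEs, and the report carries mean, sd and the empirical
2.5/97.5-percentile interval over repeats (the level is specified, the
method is the package's choice). Tracking validation leaves one
subject out, trains on all other subjects plus the left-out subject's
first four weeks, and attaches each subject's own first-four-week mean
UPDRS as a calibration column (the encoding is pluggable; a summary
column per subject is used rather than zeroing the column for other
subjects, because the latter makes the calibration invisible to the
forest at training time). Within-week phonation predictions are
averaged before the absolute error; weeks with missing sessions are
skipped, and subjects with fewer than five distinct weeks are skipped
with a log entry.

## Problem sizes

The test-suite and the reproduction script run scaled-down study
conditions chosen as the package's own desk-scale defaults: cohorts of
42 subjects with two phonation slots at the three assessment weeks
(252 phonations per arm) for the clean-vs-degraded comparison; 10-fold
CV with 5–10 repeats instead of 100; tracking on a 10-subject,
13-week, one-slot cohort; 10⁵ bits for bit-error-rate estimates. Under
these conditions the pipeline's cross-validated MAE on channel-degraded
male phonations is about 3 motor-UPDRS points against a dummy baseline
near 6.5 (clean audio: about 2.3), and clean audio is consistently at
least as accurate as degraded audio.

## Known limitations

* The severity link is linear and noise-free by construction; real
  feature–UPDRS associations are far weaker (the synthetic cohort
  over-states achievable accuracy, by design).
* Peak normalization discards the loudness channel of the severity
  link; energy-related severity information is therefore not exercised
  end-to-end.
* The codec is GSM-flavoured, not bit-exact GSM 06.10; the air
  interface (GMSK, cell handoff, frame stealing) is not modelled.
* The tracker's measured jitter under strong aspiration noise is
  inflated relative to the commanded value (a property shared by
  perturbation measures generally); only its monotonicity, not its
  calibration, should be relied on in noisy regimes.
* EMD uses a bounded sifting budget (6 IMFs, 8 siftings, sd threshold
  0.2) for speed; extremely long or pathological inputs may terminate
  early, which is reported as a missing-value reason rather than an
  error.
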