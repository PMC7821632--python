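"""Synthetic Parkinson's-disease voice cohorts.

Emulates the structure of a six-month at-home phonation trial: each
subject has UPDRS clinical assessments at baseline, three months and six
months, and weekly sessions of six sustained /ah:/ phonations (slots 1-4
at comfortable loudness, slots 5-6 at twice the comfortable loudness).
Waveforms are produced by a source-filter synthesizer (Rosenberg-style
glottal pulse train through three formant resonators) whose degradation
parameters -- jitter, shimmer, aspiration noise, F0 wander, loudness --
are a monotone function of symptom severity.

The severity link is a testing device: it lets every downstream stage be
validated against a known ground truth.  It is not a physiological claim
about how UPDRS maps onto acoustics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd

from .clinical import MOTOR_RANGE, TOTAL_RANGE, UPDRSAssessment, UPDRSTrajectory
from .phonation import Phonation

__all__ = [
    "VoiceParams",
    "SubjectProfile",
    "SessionSpec",
    "Cohort",
    "default_voice_params",
    "severity_to_voice_params",
    "synthesize_phonation",
    "generate_cohort",
    "realize_phonations",
    "write_cohort",
]

ASSESSMENT_FRACTIONS = (0.0, 0.5, 1.0)   # baseline, mid-trial, end of trial
SLOTS_COMFORTABLE = (1, 2, 3, 4)
SLOTS_LOUD = (5, 6)
LOUD_GAIN_FACTOR = 2.0                   # "twice the comfortable loudness"


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------
@dataclass(frozen=True)
class VoiceParams:
    """Acoustic control parameters for one synthesized phonation."""

    f0_mean: float                 # Hz
    jitter_frac: float = 0.004     # expected |cycle-to-cycle period diff| / period
    shimmer_frac: float = 0.025    # expected |cycle-to-cycle amplitude diff| / amplitude
    aspiration_snr_db: float = 25.0  # source-to-aspiration-noise ratio; +inf = noiseless
    f0_wander_frac: float = 0.005  # slow relative F0 drift (std)
    formants: tuple[tuple[float, float], ...] = ((700.0, 80.0), (1220.0, 100.0), (2600.0, 160.0))
    duration_s: float = 4.0
    loudness_gain: float = 1.0

    def __post_init__(self) -> None:
        if self.f0_mean <= 0:
            raise ValueError("f0_mean must be positive")
        if self.duration_s < 3.0:
            raise ValueError("duration_s must be >= 3 s (feature path needs a 3 s interior)")
        for name in ("jitter_frac", "shimmer_frac", "f0_wander_frac"):
            v = getattr(self, name)
            if not (0.0 <= v < 0.5):
                raise ValueError(f"{name} must be in [0, 0.5)")
        if self.loudness_gain <= 0:
            raise ValueError("loudness_gain must be positive")
        if not self.formants:
            raise ValueError("at least one formant required")


@dataclass(frozen=True)
class SubjectProfile:
    """Latent clinical description of one synthetic subject."""

    subject_id: str
    sex: str                      # "male" | "female"
    age: float
    baseline_motor: float
    baseline_total: float
    progression_rate: float       # UPDRS points / week (motor scale)
    n_weeks: int = 26

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError("sex must be 'male' or 'female'")
        if not (MOTOR_RANGE[0] <= self.baseline_motor <= MOTOR_RANGE[1]):
            raise ValueError("baseline_motor outside scale range")
        if not (TOTAL_RANGE[0] <= self.baseline_total <= TOTAL_RANGE[1]):
            raise ValueError("baseline_total outside scale range")
        if self.baseline_total < self.baseline_motor:
            raise ValueError("baseline_total must be >= baseline_motor")
        if not math.isfinite(self.progression_rate):
            raise ValueError("progression_rate must be finite")


@dataclass(frozen=True)
class SessionSpec:
    """One weekly recording session: exactly six phonation slots."""

    week: int
    phonation_slots: tuple[int, ...] = SLOTS_COMFORTABLE + SLOTS_LOUD

    def __post_init__(self) -> None:
        if self.week < 0:
            raise ValueError("week must be >= 0")
        if self.phonation_slots != SLOTS_COMFORTABLE + SLOTS_LOUD:
            raise ValueError("a session has exactly six slots, 1-4 comfortable then 5-6 loud")

    @staticmethod
    def loudness_of(slot: int) -> str:
        if slot in SLOTS_COMFORTABLE:
            return "comfortable"
        if slot in SLOTS_LOUD:
            return "loud"
        raise ValueError(f"invalid slot {slot}")


@dataclass
class Cohort:
    """Subjects, latent weekly UPDRS trajectories, and session specs."""

    subjects: list[SubjectProfile]
    trajectories: dict[str, UPDRSTrajectory]
    sessions: dict[str, list[SessionSpec]]
    seed: int
    link_strength: float = 1.0

    @property
    def assessment_weeks(self) -> tuple[int, ...]:
        return self.trajectories[self.subjects[0].subject_id].source_weeks

    def assessments(self, subject_id: str) -> list[UPDRSAssessment]:
        traj = self.trajectories[subject_id]
        return [
            UPDRSAssessment(week=w, motor=traj.at_week(w, "motor"), total=traj.at_week(w, "total"))
            for w in traj.source_weeks
        ]


# --------------------------------------------------------------------------
# severity -> acoustics link
# --------------------------------------------------------------------------
_BASE_F0 = {"male": 110.0, "female": 205.0}
_FORMANT_SHIFT = {"male": 1.0, "female": 1.12}

# per-UPDRS-point slopes at link_strength = 1, by sex.  Signs encode the
# direction the analysis exploits: perturbation and noise grow with
# severity, loudness and source-to-noise ratio shrink.
_LINK_SLOPES = {
    "male": {
        "jitter_frac": 2.5e-4,
        "shimmer_frac": 8.0e-4,
        "f0_wander_frac": 1.5e-4,
        "aspiration_snr_db": -0.15,
        "loudness_gain": -3.0e-3,
    },
    "female": {
        "jitter_frac": 2.0e-4,
        "shimmer_frac": 6.5e-4,
        "f0_wander_frac": 1.8e-4,
        "aspiration_snr_db": -0.12,
        "loudness_gain": -4.0e-3,
    },
}


def default_voice_params(sex: str, **overrides) -> VoiceParams:
    """Healthy-voice baseline parameters for a given sex."""
    if sex not in _BASE_F0:
        raise ValueError("sex must be 'male' or 'female'")
    shift = _FORMANT_SHIFT[sex]
    base = VoiceParams(
        f0_mean=_BASE_F0[sex],
        formants=tuple((fc * shift, bw) for fc, bw in VoiceParams.__dataclass_fields__["formants"].default),
    )
    return replace(base, **overrides) if overrides else base


def severity_to_voice_params(
    updrs: float,
    sex: str,
    base: Optional[VoiceParams] = None,
    link_strength: float = 1.0,
    seed: Optional[int] = None,
) -> VoiceParams:
    """Map a UPDRS score to voice-degradation parameters.

    The link is linear in UPDRS on each parameter, with sex-specific
    slopes scaled by ``link_strength``.  A seeded multiplicative factor
    (shared across all UPDRS values for the same seed) models
    between-subject variation in how strongly severity expresses in the
    voice; for a fixed seed the map stays exactly monotone in UPDRS.
    ``link_strength = 0`` returns ``base`` unchanged.
    """
    if link_strength < 0:
        raise ValueError("link_strength must be >= 0")
    if sex not in _LINK_SLOPES:
        raise ValueError("sex must be 'male' or 'female'")
    if not (0.0 <= updrs <= TOTAL_RANGE[1]):
        raise ValueError(f"updrs {updrs} outside scale range")
    if base is None:
        base = default_voice_params(sex)
    if link_strength == 0.0:
        return base

    factor = 1.0
    if seed is not None:
        rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0x5E]))
        factor = rng.uniform(0.8, 1.2)
    s = _LINK_SLOPES[sex]
    eff = link_strength * factor

    jitter = min(base.jitter_frac + eff * s["jitter_frac"] * updrs, 0.49)
    shimmer = min(base.shimmer_frac + eff * s["shimmer_frac"] * updrs, 0.49)
    wander = min(base.f0_wander_frac + eff * s["f0_wander_frac"] * updrs, 0.49)
    asp = base.aspiration_snr_db + eff * s["aspiration_snr_db"] * updrs
    gain = max(base.loudness_gain * (1.0 + eff * s["loudness_gain"] * updrs), 0.25 * base.loudness_gain)
    return replace(
        base,
        jitter_frac=jitter,
        shimmer_frac=shimmer,
        f0_wander_frac=wander,
        aspiration_snr_db=asp,
        loudness_gain=gain,
    )


# --------------------------------------------------------------------------
# waveform synthesis
# --------------------------------------------------------------------------
_ROSENBERG_TP = 0.40   # opening phase as a fraction of the cycle
_ROSENBERG_TN = 0.16   # closing (return) phase fraction


def _rosenberg(phase: np.ndarray) -> np.ndarray:
    """Rosenberg glottal flow pulse evaluated at cycle phase in [0, 1)."""
    g = np.zeros_like(phase)
    rise = phase < _ROSENBERG_TP
    g[rise] = 0.5 * (1.0 - np.cos(np.pi * phase[rise] / _ROSENBERG_TP))
    fall = (phase >= _ROSENBERG_TP) & (phase < _ROSENBERG_TP + _ROSENBERG_TN)
    g[fall] = np.cos(0.5 * np.pi * (phase[fall] - _ROSENBERG_TP) / _ROSENBERG_TN)
    return g


def _resonator_coeffs(fc: float, bw: float, fs: float) -> tuple[np.ndarray, np.ndarray]:
    r = math.exp(-math.pi * bw / fs)
    theta = 2.0 * math.pi * fc / fs
    a = np.array([1.0, -2.0 * r * math.cos(theta), r * r])
    b = np.array([1.0 - r])  # keeps per-stage gain bounded
    return b, a


# scale of the Gaussian period/amplitude perturbations such that the
# expected |consecutive difference| equals the commanded fraction:
# for iid N(0, sigma), E|x_i - x_{i-1}| = 2 sigma / sqrt(pi).
_PERTURB_SIGMA = math.sqrt(math.pi) / 2.0
_PEAK_TARGET = 0.35  # peak amplitude at loudness_gain = 1


def synthesize_phonation(
    params: VoiceParams,
    sample_rate: int = 24000,
    seed: int = 0,
    **provenance,
) -> Phonation:
    """Synthesize one sustained /ah:/ phonation.

    A glottal pulse train with per-cycle period perturbation
    (``jitter_frac``), slow F0 wander, and per-cycle amplitude
    perturbation (``shimmer_frac``) is mixed with white aspiration noise
    at ``aspiration_snr_db`` and shaped by a cascade of second-order
    formant resonators.  The commanded cycle lengths and amplitudes are
    recorded in ``meta`` so tests can compare extracted perturbation
    against ground truth.
    """
    from scipy.signal import lfilter

    fs = int(sample_rate)
    f_max = max(fc for fc, _ in params.formants)
    if fs < 2 * f_max:
        raise ValueError(f"sample_rate {fs} < twice the highest formant ({f_max} Hz)")

    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0xA1]))
    n_total = int(round(params.duration_s * fs))
    t0 = 1.0 / params.f0_mean

    # --- per-cycle periods and amplitudes -------------------------------
    n_cycles = int(math.ceil(params.duration_s / t0)) + 8
    jit = (
        rng.normal(0.0, params.jitter_frac * _PERTURB_SIGMA, n_cycles)
        if params.jitter_frac > 0 else np.zeros(n_cycles)
    )
    if params.f0_wander_frac > 0:
        # AR(1) drift, unit stationary variance, scaled to the commanded std
        w = np.empty(n_cycles)
        rho = 0.995
        w[0] = rng.normal()
        innov = rng.normal(0.0, math.sqrt(1 - rho * rho), n_cycles)
        for i in range(1, n_cycles):
            w[i] = rho * w[i - 1] + innov[i]
        wander = params.f0_wander_frac * w
    else:
        wander = np.zeros(n_cycles)
    periods = t0 * np.clip(1.0 + jit + wander, 0.5, 1.5)

    shim = (
        rng.normal(0.0, params.shimmer_frac * _PERTURB_SIGMA, n_cycles)
        if params.shimmer_frac > 0 else np.zeros(n_cycles)
    )
    amps = np.clip(1.0 + shim, 0.1, None)

    # --- continuous-phase pulse train ------------------------------------
    # cycle onsets live on a continuous time axis; the glottal pulse is
    # evaluated at the exact phase of every sample, so the commanded cycle
    # lengths are realized without sample-grid quantization.  The pulse
    # shape is fixed (tied to the nominal period), so perturbing the
    # onsets moves every waveform landmark one-for-one with the commanded
    # period: commanded jitter is what a cycle tracker should recover.
    onsets_t = np.concatenate([[0.0], np.cumsum(periods)])
    ts = np.arange(n_total) / fs
    idx = np.searchsorted(onsets_t, ts, side="right") - 1
    idx = np.clip(idx, 0, periods.size - 1)
    phase = (ts - onsets_t[idx]) / t0
    source = amps[idx] * _rosenberg(np.clip(phase, 0.0, 1.0))

    keep = onsets_t[:-1] < params.duration_s
    cycle_lengths_s = periods[keep]
    cycle_amps = amps[keep]
    onsets_kept = np.floor(onsets_t[:-1][keep] * fs).astype(int)

    # --- aspiration noise ----------------------------------------------
    if np.isfinite(params.aspiration_snr_db):
        p_src = float(np.mean(source**2))
        p_noise = p_src / (10.0 ** (params.aspiration_snr_db / 10.0))
        source = source + rng.normal(0.0, math.sqrt(p_noise), n_total)

    # --- formant shaping ------------------------------------------------
    out = source
    for fc, bw in params.formants:
        b, a = _resonator_coeffs(fc, bw, fs)
        out = lfilter(b, a, out)

    peak = float(np.max(np.abs(out)))
    if peak > 0:
        out = out * (_PEAK_TARGET / peak)
    out = out * params.loudness_gain
    out = np.clip(out, -1.0, 1.0)

    ph = Phonation(samples=out, sample_rate=fs, **provenance)
    ph.meta["voice_params"] = params
    ph.meta["cycle_lengths_s"] = np.asarray(cycle_lengths_s, dtype=float)
    ph.meta["cycle_amplitudes"] = np.asarray(cycle_amps, dtype=float)
    ph.meta["cycle_onsets"] = onsets_kept
    return ph


# --------------------------------------------------------------------------
# cohort generation
# --------------------------------------------------------------------------
# Clinical sampling parameters follow the published cohort description of
# the trial being emulated (mean +/- sd of baseline and six-month UPDRS).
_CLINICAL = {
    "male": dict(age=(64.8, 8.1), motor0=(20.3, 8.5), extra_total=(7.2, 4.0), motor_rate=(0.065, 0.12)),
    "female": dict(age=(63.6, 11.6), motor0=(17.6, 7.4), extra_total=(6.6, 3.5), motor_rate=(0.096, 0.14)),
}
_WOBBLE_SD = 0.5  # week-to-week Gaussian wobble around the linear trend
_TOTAL_RATE_FACTOR = 1.6  # total-UPDRS progresses faster than motor on average


def _make_subject(sex: str, idx: int, n_weeks: int, rng: np.random.Generator) -> SubjectProfile:
    c = _CLINICAL[sex]
    motor0 = float(np.clip(rng.normal(*c["motor0"]), 2.0, 60.0))
    extra = float(np.clip(rng.normal(*c["extra_total"]), 0.0, 30.0))
    return SubjectProfile(
        subject_id=f"{'M' if sex == 'male' else 'F'}{idx:03d}",
        sex=sex,
        age=float(np.clip(rng.normal(*c["age"]), 35.0, 90.0)),
        baseline_motor=motor0,
        baseline_total=min(motor0 + extra, TOTAL_RANGE[1]),
        progression_rate=float(rng.normal(*c["motor_rate"])),
        n_weeks=n_weeks,
    )


def _latent_trajectory(subject: SubjectProfile, rng: np.random.Generator) -> UPDRSTrajectory:
    weeks = np.arange(subject.n_weeks + 1)
    wobble_m = rng.normal(0.0, _WOBBLE_SD, weeks.size)
    wobble_t = wobble_m + rng.normal(0.0, 0.3, weeks.size)
    motor = np.clip(subject.baseline_motor + subject.progression_rate * weeks + wobble_m, *MOTOR_RANGE)
    total = np.clip(
        subject.baseline_total + _TOTAL_RATE_FACTOR * subject.progression_rate * weeks + wobble_t,
        *TOTAL_RANGE,
    )
    total = np.maximum(total, motor)  # total contains the motor section
    src = tuple(int(round(f * subject.n_weeks)) for f in ASSESSMENT_FRACTIONS)
    return UPDRSTrajectory(
        subject_id=subject.subject_id,
        weeks=weeks,
        motor_weekly=motor,
        total_weekly=total,
        source_weeks=src,
    )


def generate_cohort(
    n_male: int,
    n_female: int,
    n_weeks: int = 26,
    seed: int = 0,
    link_strength: float = 1.0,
) -> Cohort:
    """Generate a synthetic cohort: subjects, trajectories, session specs.

    Each subject has clinical assessments at weeks 0, n_weeks/2 and
    n_weeks (0/13/26 for the default six-month trial) and one weekly
    session of six phonation slots for every week 0..n_weeks.  Identical
    seeds give identical cohorts.
    """
    if n_male < 0 or n_female < 0 or n_male + n_female < 1:
        raise ValueError("cohort must contain at least one subject")
    if n_weeks < 2:
        raise ValueError("n_weeks must be >= 2")

    subjects: list[SubjectProfile] = []
    trajectories: dict[str, UPDRSTrajectory] = {}
    sessions: dict[str, list[SessionSpec]] = {}
    counter = 0
    for sex, count in (("male", n_male), ("female", n_female)):
        for i in range(count):
            rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0xC0, counter]))
            subj = _make_subject(sex, i + 1, n_weeks, rng)
            subjects.append(subj)
            trajectories[subj.subject_id] = _latent_trajectory(subj, rng)
            sessions[subj.subject_id] = [SessionSpec(week=w) for w in range(n_weeks + 1)]
            counter += 1
    return Cohort(
        subjects=subjects,
        trajectories=trajectories,
        sessions=sessions,
        seed=int(seed),
        link_strength=float(link_strength),
    )


def realize_phonations(
    cohort: Cohort,
    sample_rate: int = 24000,
    weeks: Optional[Sequence[int]] = None,
    slots: Optional[Sequence[int]] = None,
    duration_s: Optional[float] = None,
) -> Iterator[Phonation]:
    """Yield synthesized phonations for (a subset of) the cohort's sessions.

    ``weeks``/``slots`` restrict which sessions and slots are rendered
    (all by default).  Provenance and the subject's interpolated weekly
    UPDRS are attached to each phonation's metadata.
    """
    slot_set = tuple(slots) if slots is not None else SLOTS_COMFORTABLE + SLOTS_LOUD
    for s_idx, subj in enumerate(cohort.subjects):
        traj = cohort.trajectories[subj.subject_id]
        for sess in cohort.sessions[subj.subject_id]:
            if weeks is not None and sess.week not in weeks:
                continue
            motor = traj.at_week(sess.week, "motor")
            total = traj.at_week(sess.week, "total")
            for slot in sess.phonation_slots:
                if slot not in slot_set:
                    continue
                params = severity_to_voice_params(
                    motor, subj.sex,
                    link_strength=cohort.link_strength,
                    seed=cohort.seed * 1009 + s_idx,
                )
                if slot in SLOTS_LOUD:
                    params = replace(params, loudness_gain=params.loudness_gain * LOUD_GAIN_FACTOR)
                if duration_s is not None:
                    params = replace(params, duration_s=duration_s)
                child = np.random.SeedSequence(
                    [cohort.seed & 0x7FFFFFFF, 0xF0, s_idx, sess.week, slot]
                ).generate_state(1)[0] & 0x7FFFFFFF
                ph = synthesize_phonation(
                    params, sample_rate=sample_rate, seed=int(child),
                    subject_id=subj.subject_id, sex=subj.sex,
                    week=sess.week, slot=slot,
                    loudness=SessionSpec.loudness_of(slot),
                )
                ph.meta["motor_updrs"] = motor
                ph.meta["total_updrs"] = total
                yield ph


def write_cohort(
    cohort: Cohort,
    out_dir: str | Path,
    sample_rate: int = 24000,
    weeks: Optional[Sequence[int]] = None,
    slots: Optional[Sequence[int]] = None,
) -> pd.DataFrame:
    """Write per-slot WAV files and a tab-delimited cohort manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for ph in realize_phonations(cohort, sample_rate=sample_rate, weeks=weeks, slots=slots):
        rel = Path(ph.subject_id) / f"w{ph.week:02d}_s{ph.slot}.wav"
        ph.to_wav(out_dir / rel)
        rows.append({
            "subject_id": ph.subject_id,
            "sex": ph.sex,
            "week": ph.week,
            "slot": ph.slot,
            "loudness": ph.loudness,
            "wav_path": str(rel),
            "motor_updrs": ph.meta["motor_updrs"],
            "total_updrs": ph.meta["total_updrs"],
        })
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
    return manifest
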