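"""132-dimensional dysphonia feature extraction.

``extract_all`` runs preprocessing (middle 3 s, unit-peak normalization),
vocal-fold cycle extraction, and the nine feature families, returning a
:class:`FeatureVector` of exactly 132 named values in fixed registry
order.  Features that cannot be computed on a given signal (e.g. jitter
on an unvoiced recording) are carried as NaN together with a reason;
imputation is a modelling-time concern, never applied at extraction.

Band-based and recurrence measures (GNE, VFER, EMD-ER, RPDE) are
evaluated at a fixed 8 kHz analysis rate -- the telephone-channel output
rate -- so that the 2.5 kHz signal/noise split means the same thing for
clean wide-band and channel-degraded recordings (noise band [2.5, 4] kHz).
Inputs at other rates are resampled internally for those families only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy.signal import resample_poly

from ..phonation import Phonation
from . import registry
from .cycles import CycleSequence, extract_cycles, frame_f0
from .emd import emd, emd_er_features
from .f0stats import F0_NORMS_HZ, f0_family
from .nonlinear import dfa, dfa_exponent, ppe, rpde
from .noise_ratios import ANALYSIS_RATE, gne_features, hnr_features, vfer_features
from .perturbation import gq_features, jitter_family, shimmer_family
from .preprocess import SEGMENT_S, TooShortError, preprocess
from .registry import FAMILIES, FAMILY_OF, N_FEATURES, REGISTRY
from .spectral import mfcc_family

__all__ = [
    "FeatureVector", "extract_all", "extract_table",
    "preprocess", "extract_cycles", "frame_f0", "CycleSequence",
    "jitter_family", "shimmer_family", "gq_features", "hnr_features",
    "gne_features", "vfer_features", "emd", "emd_er_features",
    "rpde", "dfa", "dfa_exponent", "ppe", "mfcc_family", "f0_family",
    "hnr_gq_family", "nonlinear_family", "snr_band_family",
    "registry", "REGISTRY", "FAMILIES", "N_FEATURES", "TooShortError",
    "ANALYSIS_RATE", "F0_NORMS_HZ", "SEGMENT_S",
]


@dataclass
class FeatureVector:
    """Named 132-entry dysphonia feature vector with missing-value reasons."""

    values: dict[str, float]
    missing: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if list(self.values.keys()) != REGISTRY:
            raise ValueError("feature vector must carry the 132 registry names in order")

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, dtype=float)

    def family(self, name: str) -> dict[str, float]:
        return {k: self.values[k] for k in FAMILIES[name]}

    def __len__(self) -> int:
        return len(self.values)


def _to_analysis_rate(x: np.ndarray, fs: int) -> tuple[np.ndarray, int]:
    if fs == ANALYSIS_RATE:
        return x, fs
    from math import gcd
    g = gcd(fs, ANALYSIS_RATE)
    return resample_poly(x, ANALYSIS_RATE // g, fs // g), ANALYSIS_RATE


# ----------------------------------------------------------------- grouped
# family operations exposed at the granularity used by the pipeline
def hnr_gq_family(phonation: Phonation, cycles: CycleSequence) -> dict[str, float]:
    """HNR/NHR plus Glottal Quotient variants (7 values)."""
    out = hnr_features(cycles)
    out.update(gq_features(phonation.samples, phonation.sample_rate, cycles))
    return out


def nonlinear_family(phonation: Phonation, cycles: CycleSequence) -> dict[str, float]:
    """RPDE, DFA and PPE (3 values)."""
    x8, fs8 = _to_analysis_rate(phonation.samples, phonation.sample_rate)
    return {
        "rpde": rpde(x8, fs8),
        "dfa": dfa(phonation.samples),
        "ppe": ppe(cycles),
    }


def snr_band_family(phonation: Phonation) -> dict[str, float]:
    """GNE, VFER and EMD-ER measures (21 values) at the 8 kHz analysis rate."""
    x8, fs8 = _to_analysis_rate(phonation.samples, phonation.sample_rate)
    out = gne_features(x8, fs8)
    out.update(vfer_features(x8, fs8))
    out.update(emd_er_features(x8, fs8))
    return out


def extract_all(
    phonation: Phonation,
    sex: Optional[str] = None,
    f0_norms: Optional[dict[str, float]] = None,
) -> FeatureVector:
    """Compute the full 132-feature dysphonia vector for one phonation.

    The input must be at least 3 s long; preprocessing (trim + normalize)
    is applied internally.  ``sex`` (defaulting to the phonation's
    provenance) is needed for the normative F0 comparison.
    """
    sex = sex or phonation.sex
    seg = preprocess(phonation)
    cycles = extract_cycles(seg)

    values: dict[str, float] = {name: np.nan for name in REGISTRY}
    missing: dict[str, str] = {}

    def run(family: str, fn) -> None:
        try:
            out = fn()
        except (ValueError, ZeroDivisionError, FloatingPointError) as exc:
            for name in FAMILIES[family]:
                missing[name] = str(exc)
            return
        for name in FAMILIES[family]:
            v = out[name]
            if not np.isfinite(v):
                missing[name] = "non-finite result"
                values[name] = np.nan
            else:
                values[name] = float(v)

    run("jitter", lambda: jitter_family(cycles))
    run("shimmer", lambda: shimmer_family(cycles))
    run("hnr_gq", lambda: hnr_gq_family(seg, cycles))
    run("nonlinear", lambda: nonlinear_family(seg, cycles))

    x8, fs8 = _to_analysis_rate(seg.samples, seg.sample_rate)
    run("gne", lambda: gne_features(x8, fs8))
    run("vfer", lambda: vfer_features(x8, fs8))
    run("emd", lambda: emd_er_features(x8, fs8))
    run("mfcc", lambda: mfcc_family(seg.samples, seg.sample_rate))
    run("f0", lambda: f0_family(cycles, sex, f0_norms))

    return FeatureVector(values=values, missing=missing)


def extract_table(
    phonations: Iterable[Phonation],
    f0_norms: Optional[dict[str, float]] = None,
) -> pd.DataFrame:
    """Feature table for many phonations: 132 registry columns plus
    provenance columns (subject_id, sex, week, slot, loudness and any
    UPDRS scores found in metadata)."""
    rows = []
    for ph in phonations:
        fv = extract_all(ph, f0_norms=f0_norms)
        row: dict[str, object] = {
            "subject_id": ph.subject_id,
            "sex": ph.sex,
            "week": ph.week,
            "slot": ph.slot,
            "loudness": ph.loudness,
        }
        for key in ("motor_updrs", "total_updrs"):
            if key in ph.meta:
                row[key] = ph.meta[key]
        row.update(fv.values)
        rows.append(row)
    return pd.DataFrame(rows)
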