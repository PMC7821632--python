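"""Segment trimming and amplitude normalization.

Feature extraction operates on the central three seconds of each
phonation (vowel onset/offset removed) normalized to unit peak
amplitude.  The applied gain is recorded in the phonation's metadata so
gain-sensitive quantities (log energy) can be reconstructed if needed.
"""

from __future__ import annotations

import numpy as np

from ..phonation import Phonation

SEGMENT_S = 3.0

__all__ = ["TooShortError", "preprocess", "SEGMENT_S"]


class TooShortError(ValueError):
    """Raised when a phonation is shorter than the 3 s analysis segment."""


def preprocess(phonation: Phonation) -> Phonation:
    """Return the middle 3 s, peak-normalized; sample rate preserved."""
    fs = phonation.sample_rate
    n_seg = int(round(SEGMENT_S * fs))
    n = phonation.samples.size
    if n < n_seg:
        raise TooShortError(
            f"phonation is {n / fs:.2f} s; at least {SEGMENT_S} s required"
        )
    start = (n - n_seg) // 2
    segment = phonation.samples[start:start + n_seg].copy()
    peak = float(np.max(np.abs(segment)))
    gain = 1.0 / peak if peak > 0 else 1.0
    out = phonation.with_samples(segment * gain)
    out.meta["preprocess_gain"] = gain
    out.meta["preprocess_start_s"] = start / fs
    out.meta["normalization"] = "unit_peak"
    return out
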