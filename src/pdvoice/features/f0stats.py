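"""F0 distribution summaries and normative deviation features.

The deviation features compare the subject's mean F0 with a configurable
sex-specific normative value for healthy voices (defaults 120 Hz male /
210 Hz female, typical adult sustained-vowel values).
"""

from __future__ import annotations

import numpy as np

from .cycles import CycleSequence
from .registry import F0_FEATURES

__all__ = ["f0_family", "F0_NORMS_HZ"]

F0_NORMS_HZ = {"male": 120.0, "female": 210.0}


def f0_family(
    cycles: CycleSequence,
    sex: str,
    norms: dict[str, float] | None = None,
) -> dict[str, float]:
    """Eight F0 summary features from the per-cycle F0 contour."""
    if not cycles.voiced or cycles.n_cycles < 3:
        raise ValueError("F0 family requires a voiced contour of >= 3 cycles")
    if sex not in ("male", "female"):
        raise ValueError("sex must be 'male' or 'female'")
    norm = (norms or F0_NORMS_HZ)[sex]
    f0 = cycles.f0_contour
    mean = float(np.mean(f0))
    return dict(zip(F0_FEATURES, [
        mean,
        float(np.median(f0)),
        float(np.std(f0)),
        float(np.min(f0)),
        float(np.max(f0)),
        float(np.max(f0) - np.min(f0)),
        mean - norm,
        (mean - norm) / norm,
    ]))
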