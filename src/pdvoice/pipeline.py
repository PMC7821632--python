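"""End-to-end convenience layer: cohort -> (degraded) audio -> feature table.

Glue used by the examples, the command-line interface and the
reproduction script; everything here is a thin composition of the
public module functions.
"""

from __future__ import annotations

from typing import Optional, Sequence

import pandas as pd

from .channel import ChannelConfig, degrade
from .cohort import Cohort, realize_phonations
from .features import extract_all

__all__ = ["cohort_feature_table"]


def cohort_feature_table(
    cohort: Cohort,
    channel: Optional[ChannelConfig] = None,
    sample_rate: int = 24000,
    weeks: Optional[Sequence[int]] = None,
    slots: Optional[Sequence[int]] = None,
    duration_s: Optional[float] = None,
) -> pd.DataFrame:
    """Synthesize (a subset of) a cohort and extract the 132 measures.

    With a :class:`ChannelConfig`, every phonation is passed through the
    full transmission chain before feature extraction (each phonation
    gets its own deterministic channel seed derived from the config
    seed); without one, features are computed on the clean wide-band
    audio.  Returns one row per phonation: provenance columns, the
    weekly UPDRS responses, and the 132 registry features.
    """
    rows = []
    for i, ph in enumerate(
        realize_phonations(cohort, sample_rate=sample_rate, weeks=weeks,
                           slots=slots, duration_s=duration_s)
    ):
        if channel is not None:
            from dataclasses import replace
            cfg = replace(channel, seed=(channel.seed * 100003 + i) & 0x7FFFFFFF)
            ph_out = degrade(ph, cfg)
        else:
            ph_out = ph
        fv = extract_all(ph_out, sex=ph.sex)
        row = {
            "subject_id": ph.subject_id,
            "sex": ph.sex,
            "week": ph.week,
            "slot": ph.slot,
            "loudness": ph.loudness,
            "motor_updrs": ph.meta["motor_updrs"],
            "total_updrs": ph.meta["total_updrs"],
        }
        row.update(fv.values)
        rows.append(row)
    return pd.DataFrame(rows)
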