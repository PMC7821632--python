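"""Waveform container and WAV I/O for sustained-vowel phonations.

A :class:`Phonation` couples a mono floating-point waveform with the
provenance needed downstream: who phonated, when, at which loudness
condition, and at what sample rate.  Audio is stored as float64 in
[-1, 1]; files are written as 16-bit PCM WAV.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Optional

import numpy as np
from scipy.io import wavfile

__all__ = ["Phonation"]

_PCM16_SCALE = 32767.0


@dataclass
class Phonation:
    """A sampled sustained-vowel waveform plus recording provenance."""

    samples: np.ndarray
    sample_rate: int
    subject_id: Optional[str] = None
    sex: Optional[str] = None          # "male" | "female"
    week: Optional[int] = None
    slot: Optional[int] = None         # 1..6 within a session
    loudness: Optional[str] = None     # "comfortable" | "loud"
    bit_depth: int = 16
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("phonation waveform must be mono (1-D)")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate

    def with_samples(self, samples: np.ndarray, sample_rate: int | None = None) -> "Phonation":
        """Copy provenance onto a new waveform."""
        return replace(
            self,
            samples=np.asarray(samples, dtype=np.float64),
            sample_rate=int(sample_rate or self.sample_rate),
            meta=dict(self.meta),
        )

    # ------------------------------------------------------------------ I/O
    def to_wav(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        clipped = np.clip(self.samples, -1.0, 1.0)
        wavfile.write(path, self.sample_rate, (clipped * _PCM16_SCALE).astype(np.int16))
        return path

    @classmethod
    def from_wav(cls, path: str | Path, **provenance: Any) -> "Phonation":
        rate, data = wavfile.read(path)
        if data.ndim > 1:
            data = data[:, 0]
        if np.issubdtype(data.dtype, np.integer):
            data = data.astype(np.float64) / float(np.iinfo(data.dtype).max)
        else:
            data = data.astype(np.float64)
        return cls(samples=data, sample_rate=int(rate), **provenance)
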