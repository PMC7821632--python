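"""UPDRS clinical-score containers shared by the cohort generator and the
response-preparation stage.

Motor-UPDRS lies in [0, 108], total-UPDRS in [0, 176]; higher is more
severe.  Assessments are sparse (baseline / three months / six months);
weekly values are obtained by piecewise-linear interpolation that passes
exactly through the measured assessments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

MOTOR_RANGE = (0.0, 108.0)
TOTAL_RANGE = (0.0, 176.0)

__all__ = ["UPDRSAssessment", "UPDRSTrajectory", "MOTOR_RANGE", "TOTAL_RANGE"]


@dataclass(frozen=True)
class UPDRSAssessment:
    """One clinical visit: motor and total UPDRS at a given trial week."""

    week: int
    motor: float
    total: float

    def __post_init__(self) -> None:
        if not (MOTOR_RANGE[0] <= self.motor <= MOTOR_RANGE[1]):
            raise ValueError(f"motor-UPDRS {self.motor} outside {MOTOR_RANGE}")
        if not (TOTAL_RANGE[0] <= self.total <= TOTAL_RANGE[1]):
            raise ValueError(f"total-UPDRS {self.total} outside {TOTAL_RANGE}")
        if self.total < self.motor:
            raise ValueError("total-UPDRS cannot be below motor-UPDRS")


@dataclass
class UPDRSTrajectory:
    """Weekly UPDRS values for one subject.

    ``source_weeks`` records the weeks at which the scores were actually
    measured; values at other weeks are interpolated (analysis side) or
    simulated (synthetic-cohort side).
    """

    subject_id: str
    weeks: np.ndarray          # integer weeks, ascending
    motor_weekly: np.ndarray
    total_weekly: np.ndarray
    source_weeks: tuple[int, ...]

    def __post_init__(self) -> None:
        self.weeks = np.asarray(self.weeks, dtype=int)
        self.motor_weekly = np.asarray(self.motor_weekly, dtype=float)
        self.total_weekly = np.asarray(self.total_weekly, dtype=float)
        if not (self.weeks.size == self.motor_weekly.size == self.total_weekly.size):
            raise ValueError("weeks/motor/total lengths differ")
        if np.any(np.diff(self.weeks) <= 0):
            raise ValueError("weeks must be strictly increasing")

    def at_week(self, week: int, response: str = "motor") -> float:
        values = self.motor_weekly if response == "motor" else self.total_weekly
        idx = np.nonzero(self.weeks == week)[0]
        if idx.size == 0:
            raise KeyError(f"week {week} not in trajectory")
        return float(values[idx[0]])
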