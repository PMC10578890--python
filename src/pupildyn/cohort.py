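"""Patient-level data model: observations, records, and the outcome dichotomy.

A patient's stay is a sequence of bedside pupil readings on a nominal 2-hour
grid, together with the hour at which analgosedation ended, the ICU discharge
hour, and the 6-month Glasgow Outcome Scale Extended (GOSE, 1-8). Outcome is
dichotomized at GOSE > 4 (favorable) versus GOSE <= 4 (unfavorable).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

from .states import PhotoReactivityState, PupilSizeState


class Outcome(str, Enum):
    FAVORABLE = "FAVORABLE"
    UNFAVORABLE = "UNFAVORABLE"


def outcome_from_gose(gose_6m: int) -> Outcome:
    """Dichotomize the 6-month GOSE: favorable iff GOSE > 4."""
    if not 1 <= gose_6m <= 8:
        raise ValueError(f"GOSE must be in 1..8, got {gose_6m}")
    return Outcome.FAVORABLE if gose_6m > 4 else Outcome.UNFAVORABLE


class CohortValidationError(ValueError):
    """Raised when a record violates the data-model invariants."""


@dataclass(frozen=True)
class PupilObservation:
    """One bedside reading: hours since ICU admission plus both pupil states."""

    time_h: float
    ps: PupilSizeState
    pr: PhotoReactivityState

    def __post_init__(self) -> None:
        if self.time_h < 0:
            raise CohortValidationError(f"observation time must be >= 0, got {self.time_h}")


@dataclass
class PatientRecord:
    """One patient's observation series plus outcome metadata.

    Invariants enforced on construction: strictly increasing observation
    times, all times <= discharge, at least two observations, outcome label
    consistent with the GOSE dichotomy, 0 < sedation_stop <= discharge.
    """

    patient_id: str
    observations: list[PupilObservation]
    sedation_stop_h: float
    discharge_h: float
    gose_6m: int
    outcome: Outcome = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.outcome is None:
            self.outcome = outcome_from_gose(self.gose_6m)
        self.validate()

    def validate(self) -> None:
        pid = self.patient_id
        if len(self.observations) < 2:
            raise CohortValidationError(f"{pid}: at least 2 observations required")
        times = [o.time_h for o in self.observations]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise CohortValidationError(f"{pid}: observation times must be strictly increasing")
        if not self.sedation_stop_h > 0:
            raise CohortValidationError(f"{pid}: sedation_stop must be > 0")
        if self.discharge_h < self.sedation_stop_h:
            raise CohortValidationError(f"{pid}: discharge must be >= sedation_stop")
        if times[-1] > self.discharge_h:
            raise CohortValidationError(f"{pid}: observation times must not exceed discharge")
        expected = outcome_from_gose(self.gose_6m)
        if self.outcome != expected:
            raise CohortValidationError(
                f"{pid}: outcome {self.outcome.value} inconsistent with GOSE {self.gose_6m} "
                f"(dichotomy favorable iff GOSE > 4 implies {expected.value})"
            )

    @property
    def times(self) -> list[float]:
        return [o.time_h for o in self.observations]

    @property
    def ps_series(self) -> list[PupilSizeState]:
        return [o.ps for o in self.observations]

    @property
    def pr_series(self) -> list[PhotoReactivityState]:
        return [o.pr for o in self.observations]


def split_by_outcome(
    cohort: Sequence[PatientRecord],
) -> tuple[list[PatientRecord], list[PatientRecord]]:
    """Return (favorable, unfavorable) sublists preserving order."""
    fav = [p for p in cohort if p.outcome is Outcome.FAVORABLE]
    unf = [p for p in cohort if p.outcome is Outcome.UNFAVORABLE]
    return fav, unf
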