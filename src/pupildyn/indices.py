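"""The four dynamical pupillary indices and their window-based evaluation.

For a categorical series of N observations within a time window:

* jump rate — number of consecutive-observation state changes divided by the
  number of measurements N (the per-measurement denominator; a per-transition
  N-1 denominator is available as an option),
* occupancy percentage — fraction of observations in the normal state
  (isochoria for pupil size, bilateral presence for photo-reactivity).

Windows are half-open ``[start, end)``; an observation exactly on a boundary
belongs to the later window. Missing grid points simply contribute nothing,
and a state change across a gap counts as one change.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import pandas as pd

from .cohort import PatientRecord
from .states import PR_NORMAL, PS_NORMAL

JumpDenominator = Literal["per_measurement", "per_transition"]


class UndefinedIndexError(ValueError):
    """An index is undefined on the given series (too few observations)."""


@dataclass(frozen=True)
class TimeWindow:
    """Half-open analysis window [start, end), in hours since admission."""

    start_h: float
    end_h: float
    label: str = ""

    def __post_init__(self) -> None:
        if not self.start_h < self.end_h:
            raise ValueError(f"window start must be < end, got [{self.start_h}, {self.end_h})")


@dataclass(frozen=True)
class IndexSet:
    """The four indices evaluated on one window; NaN marks an undefined index."""

    ps_jump_rate: float
    ps_isochoria_pct: float
    pr_jump_rate: float
    pr_presence_pct: float
    n_obs: int
    window: TimeWindow

    def as_dict(self) -> dict[str, float]:
        return {
            "ps_jump_rate": self.ps_jump_rate,
            "ps_isochoria_pct": self.ps_isochoria_pct,
            "pr_jump_rate": self.pr_jump_rate,
            "pr_presence_pct": self.pr_presence_pct,
        }

    @property
    def is_missing(self) -> bool:
        return self.n_obs == 0


INDEX_NAMES = ("ps_jump_rate", "ps_isochoria_pct", "pr_jump_rate", "pr_presence_pct")


def jump_rate(states: Sequence, denominator: JumpDenominator = "per_measurement") -> float:
    """Ratio of consecutive state changes to the number of measurements.

    With N measurements there are N-1 consecutive pairs, so the result lies in
    [0, (N-1)/N] under the default per-measurement denominator.
    """
    n = len(states)
    if n < 2:
        raise UndefinedIndexError(f"jump rate needs >= 2 observations, got {n}")
    changes = sum(a != b for a, b in zip(states, states[1:]))
    denom = n if denominator == "per_measurement" else n - 1
    return changes / denom


def occupancy_pct(states: Sequence, normal_state) -> float:
    """Fraction of observations equal to the normal state, in [0, 1]."""
    if len(states) == 0:
        raise UndefinedIndexError("occupancy is undefined on an empty series")
    return sum(s == normal_state for s in states) / len(states)


def _window_obs(patient: PatientRecord, window: TimeWindow):
    return [o for o in patient.observations if window.start_h <= o.time_h < window.end_h]


def indices_for_window(
    patient: PatientRecord,
    window: TimeWindow,
    denominator: JumpDenominator = "per_measurement",
) -> IndexSet:
    """Evaluate the four indices on the observations falling in the window.

    Indices that are undefined on the windowed series (no observations for the
    occupancies, fewer than two for the jump rates) come back as NaN rather
    than zero.
    """
    obs = _window_obs(patient, window)
    n = len(obs)
    ps = [o.ps for o in obs]
    pr = [o.pr for o in obs]
    nan = float("nan")
    return IndexSet(
        ps_jump_rate=jump_rate(ps, denominator) if n >= 2 else nan,
        ps_isochoria_pct=occupancy_pct(ps, PS_NORMAL) if n >= 1 else nan,
        pr_jump_rate=jump_rate(pr, denominator) if n >= 2 else nan,
        pr_presence_pct=occupancy_pct(pr, PR_NORMAL) if n >= 1 else nan,
        n_obs=n,
        window=window,
    )


def cumulative_window(nd: int) -> TimeWindow:
    """Cumulative window for 'number of days' ND: [0, 24*(ND+1)) hours.

    ND = 0 is the first day of stay, so a "day 0" model is estimable from the
    first 24 h of data.
    """
    if nd < 0:
        raise ValueError("ND must be >= 0")
    return TimeWindow(0.0, 24.0 * (nd + 1), label=f"nd{nd}")


def index_timecourse(
    patient: PatientRecord,
    resolution: Literal["per_day", "cumulative_days"] = "per_day",
    max_nd: int = 10,
    denominator: JumpDenominator = "per_measurement",
) -> list[IndexSet]:
    """Per-day or running-cumulative index trajectories over the stay.

    ``per_day`` evaluates every calendar day [24k, 24(k+1)) up to discharge;
    ``cumulative_days`` evaluates [0, 24(ND+1)) for ND = 0..min(max_nd, last
    full day of stay).
    """
    last = patient.times[-1]
    if resolution == "per_day":
        # the day window containing the last observation is included
        n_days = int(last // 24.0) + 1
        return [
            indices_for_window(
                patient, TimeWindow(24.0 * k, 24.0 * (k + 1), label=f"day{k}"), denominator
            )
            for k in range(n_days)
        ]
    if resolution == "cumulative_days":
        nd_max = min(max_nd, int(last // 24.0))
        return [
            indices_for_window(patient, cumulative_window(nd), denominator)
            for nd in range(nd_max + 1)
        ]
    raise ValueError(f"unknown resolution {resolution!r}")


def pre_post_indices(
    patient: PatientRecord, denominator: JumpDenominator = "per_measurement"
) -> tuple[IndexSet, IndexSet]:
    """Indices during sedation [0, stop) and after it [stop, discharge].

    A patient without post-sedation observations gets a POST IndexSet with
    n_obs = 0 (all-NaN); the caller excludes such patients from paired tests.
    """
    stop = patient.sedation_stop_h
    pre = indices_for_window(patient, TimeWindow(0.0, stop, label="pre"), denominator)
    # POST is inclusive of discharge; +1 keeps the half-open convention while
    # admitting an observation exactly at discharge.
    post = indices_for_window(
        patient, TimeWindow(stop, patient.discharge_h + 1.0, label="post"), denominator
    )
    return pre, post


def cohort_prepost_table(
    cohort: Iterable[PatientRecord], denominator: JumpDenominator = "per_measurement"
) -> pd.DataFrame:
    """Long table: patient_id, outcome, period (pre/post), index values, n_obs."""
    rows = []
    for p in cohort:
        for period, idx in zip(("pre", "post"), pre_post_indices(p, denominator)):
            rows.append(
                {
                    "patient_id": p.patient_id,
                    "outcome": p.outcome.value,
                    "period": period,
                    "n_obs": idx.n_obs,
                    **idx.as_dict(),
                }
            )
    return pd.DataFrame(rows)


def cohort_cumulative_table(
    cohort: Iterable[PatientRecord],
    max_nd: int = 10,
    denominator: JumpDenominator = "per_measurement",
) -> pd.DataFrame:
    """Long table of cumulative-window indices: one row per patient per ND.

    Every patient is evaluated at every ND 0..max_nd (the cumulative window
    always contains the admission-day observations, so rows are complete for
    any stay of at least one day).
    """
    rows = []
    for p in cohort:
        for nd in range(max_nd + 1):
            idx = indices_for_window(p, cumulative_window(nd), denominator)
            rows.append(
                {
                    "patient_id": p.patient_id,
                    "outcome": p.outcome.value,
                    "nd": nd,
                    "n_obs": idx.n_obs,
                    **idx.as_dict(),
                }
            )
    return pd.DataFrame(rows)
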