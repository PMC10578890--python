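"""Synthetic cohort generator for categorical pupillary time series.

Each patient's pupil-size (PS) and photo-reactivity (PR) series is a
first-order Markov chain on the categorical state alphabet, sampled on a
2-hour grid. The chain switches transition matrix once, at the end of
sedation: favorable-outcome patients are stable and predominantly normal in
both regimes, while unfavorable-outcome patients switch states frequently
during sedation and then settle toward pathological states — the qualitative
stay-long pattern seen in TBI coma cohorts. Stay and sedation lengths are
truncated-normal draws on the scales reported for such cohorts (stay
17 +/- 9 days, sedation 9 +/- 6 days), yielding on the order of 190
observations per patient at the 2-hour cadence.

The PS and PR chains are sampled independently within a patient; their
cross-correlation is not a modelling target.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .cohort import Outcome, PatientRecord, PupilObservation
from .states import PR_STATES, PS_STATES, PhotoReactivityState, PupilSizeState

_ROW_TOL = 1e-9


def _validate_stochastic(matrix: np.ndarray, name: str, size: int) -> np.ndarray:
    m = np.asarray(matrix, dtype=float)
    if m.shape != (size, size):
        raise ValueError(f"{name}: expected shape {(size, size)}, got {m.shape}")
    if np.any(m < 0) or np.any(m > 1):
        bad = int(np.argwhere((m < 0) | (m > 1))[0][0])
        raise ValueError(f"{name}: row {bad} has entries outside [0, 1]")
    sums = m.sum(axis=1)
    off = np.abs(sums - 1.0) > _ROW_TOL
    if off.any():
        bad = int(np.argmax(off))
        raise ValueError(f"{name}: row {bad} sums to {sums[bad]:.12f}, not 1")
    return m


def _validate_dist(p: np.ndarray, name: str, size: int) -> np.ndarray:
    v = np.asarray(p, dtype=float)
    if v.shape != (size,):
        raise ValueError(f"{name}: expected length {size}")
    if np.any(v < 0) or abs(v.sum() - 1.0) > _ROW_TOL:
        raise ValueError(f"{name}: not a probability distribution")
    return v


@dataclass
class GroupDynamicsParams:
    """Markov dynamics for one outcome group: pre- and post-sedation regimes.

    ``ps_*`` matrices are 5x5 over the PS alphabet, ``pr_*`` 4x4 over the PR
    alphabet, rows in the canonical state order; every row must sum to 1
    within 1e-9.
    """

    ps_transition: np.ndarray
    pr_transition: np.ndarray
    ps_transition_post: np.ndarray
    pr_transition_post: np.ndarray
    ps_initial: np.ndarray
    pr_initial: np.ndarray

    def __post_init__(self) -> None:
        self.ps_transition = _validate_stochastic(self.ps_transition, "ps_transition", 5)
        self.pr_transition = _validate_stochastic(self.pr_transition, "pr_transition", 4)
        self.ps_transition_post = _validate_stochastic(self.ps_transition_post, "ps_transition_post", 5)
        self.pr_transition_post = _validate_stochastic(self.pr_transition_post, "pr_transition_post", 4)
        self.ps_initial = _validate_dist(self.ps_initial, "ps_initial", 5)
        self.pr_initial = _validate_dist(self.pr_initial, "pr_initial", 4)

    def to_dict(self) -> dict:
        return {k: np.asarray(v).tolist() for k, v in asdict(self).items()}

    @classmethod
    def from_dict(cls, d: dict) -> "GroupDynamicsParams":
        return cls(**{k: np.asarray(v) for k, v in d.items()})


def default_favorable_params() -> GroupDynamicsParams:
    """Stable, predominantly normal dynamics (favorable outcome).

    Isochoric self-transition 0.96 during sedation and 0.97 after, with the
    post-sedation regime chosen to hold the stationary isochoric occupancy at
    its sedation-era value (~0.94) while jumping slows — these patients are
    consistently normal throughout the stay.
    """
    ps_pre = np.array(
        [
            [0.96, 0.01, 0.01, 0.01, 0.01],
            [0.60, 0.37, 0.01, 0.01, 0.01],
            [0.60, 0.01, 0.37, 0.01, 0.01],
            [0.60, 0.01, 0.01, 0.37, 0.01],
            [0.60, 0.01, 0.01, 0.01, 0.37],
        ]
    )
    ps_post = np.array(
        [
            [0.97, 0.0075, 0.0075, 0.0075, 0.0075],
            [0.45, 0.52, 0.01, 0.01, 0.01],
            [0.45, 0.01, 0.52, 0.01, 0.01],
            [0.45, 0.01, 0.01, 0.52, 0.01],
            [0.45, 0.01, 0.01, 0.01, 0.52],
        ]
    )
    pr_pre = np.array(
        [
            [0.97, 0.01, 0.01, 0.01],
            [0.60, 0.38, 0.01, 0.01],
            [0.60, 0.01, 0.38, 0.01],
            [0.60, 0.01, 0.01, 0.38],
        ]
    )
    pr_post = np.array(
        [
            [0.99, 0.004, 0.003, 0.003],
            [0.80, 0.18, 0.01, 0.01],
            [0.80, 0.01, 0.18, 0.01],
            [0.80, 0.01, 0.01, 0.18],
        ]
    )
    return GroupDynamicsParams(
        ps_transition=ps_pre,
        pr_transition=pr_pre,
        ps_transition_post=ps_post,
        pr_transition_post=pr_post,
        ps_initial=np.array([0.9, 0.025, 0.025, 0.025, 0.025]),
        pr_initial=np.array([0.9, 0.04, 0.03, 0.03]),
    )


def default_unfavorable_params() -> GroupDynamicsParams:
    """Unstable dynamics that settle toward pathological states (unfavorable).

    Pupil size: during sedation the isochoric self-transition is only 0.70
    with frequent excursions; after sedation ends all size states become
    quasi-absorbing (self-transitions 0.95-0.97) so jumping nearly stops and
    each series freezes near its sedation-era occupancy (~0.4 isochoric) —
    stabilization toward pathological values without a change in mean
    occupancy. Photo-reactivity is affected more mildly during sedation but
    reflex presence declines after it ends (0.82 -> 0.6 occupancy), making
    reactivity the weaker between-group discriminator of the two exams while
    still showing a period-by-outcome interaction.
    """
    ps_pre = np.array(
        [
            [0.70, 0.075, 0.075, 0.075, 0.075],
            [0.30, 0.40, 0.10, 0.10, 0.10],
            [0.30, 0.10, 0.40, 0.10, 0.10],
            [0.30, 0.10, 0.10, 0.40, 0.10],
            [0.30, 0.10, 0.10, 0.10, 0.40],
        ]
    )
    ps_post = np.array(
        [
            [0.975, 0.00625, 0.00625, 0.00625, 0.00625],
            [0.025, 0.945, 0.01, 0.01, 0.01],
            [0.025, 0.01, 0.945, 0.01, 0.01],
            [0.025, 0.01, 0.01, 0.945, 0.01],
            [0.025, 0.01, 0.01, 0.01, 0.945],
        ]
    )
    pr_pre = np.array(
        [
            [0.88, 0.04, 0.04, 0.04],
            [0.55, 0.35, 0.05, 0.05],
            [0.55, 0.05, 0.35, 0.05],
            [0.55, 0.05, 0.05, 0.35],
        ]
    )
    pr_post = np.array(
        [
            [0.92, 0.03, 0.03, 0.02],
            [0.12, 0.80, 0.04, 0.04],
            [0.12, 0.04, 0.80, 0.04],
            [0.12, 0.04, 0.04, 0.80],
        ]
    )
    return GroupDynamicsParams(
        ps_transition=ps_pre,
        pr_transition=pr_pre,
        ps_transition_post=ps_post,
        pr_transition_post=pr_post,
        ps_initial=np.array([0.4, 0.15, 0.15, 0.15, 0.15]),
        pr_initial=np.array([0.75, 0.09, 0.08, 0.08]),
    )


@dataclass
class CohortConfig:
    """Cohort-level simulation settings.

    Stay and sedation lengths (days) are truncated-normal, truncated below at
    1 day, with sedation clipped to the stay; both are rounded to the 2-h grid.
    ``missingness`` drops each grid point independently with that probability.
    """

    n_favorable: int = 14
    n_unfavorable: int = 6
    stay_mean_days: float = 17.0
    stay_sd_days: float = 9.0
    sedation_mean_days: float = 9.0
    sedation_sd_days: float = 6.0
    interval_h: float = 2.0
    missingness: float = 0.0
    seed: int = 0
    favorable_params: GroupDynamicsParams = field(default_factory=default_favorable_params)
    unfavorable_params: GroupDynamicsParams = field(default_factory=default_unfavorable_params)

    def __post_init__(self) -> None:
        if self.n_favorable < 1 or self.n_unfavorable < 1:
            raise ValueError("group counts must be >= 1")
        if self.stay_sd_days < 0 or self.sedation_sd_days < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.interval_h <= 0:
            raise ValueError("sampling interval must be > 0")
        if not 0 <= self.missingness < 1:
            raise ValueError("missingness must be in [0, 1)")

    def to_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in (
                "n_favorable", "n_unfavorable", "stay_mean_days", "stay_sd_days",
                "sedation_mean_days", "sedation_sd_days", "interval_h",
                "missingness", "seed",
            )
        }
        d["favorable_params"] = self.favorable_params.to_dict()
        d["unfavorable_params"] = self.unfavorable_params.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        for key in ("favorable_params", "unfavorable_params"):
            if key in d and isinstance(d[key], dict):
                d[key] = GroupDynamicsParams.from_dict(d[key])
        return cls(**d)


def _sample_chain(transition_pre: np.ndarray, transition_post: np.ndarray,
                  initial: np.ndarray, times: np.ndarray, sedation_stop: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Sample a regime-switching Markov chain at the given grid times.

    The pre-sedation matrix governs transitions into observations taken
    strictly before ``sedation_stop``; later transitions use the post matrix.
    """
    cum_pre = np.cumsum(transition_pre, axis=1)
    cum_post = np.cumsum(transition_post, axis=1)
    u = rng.random(len(times))
    states = np.empty(len(times), dtype=np.intp)
    states[0] = np.searchsorted(np.cumsum(initial), u[0], side="right")
    for i in range(1, len(times)):
        cum = cum_pre if times[i] < sedation_stop else cum_post
        states[i] = np.searchsorted(cum[states[i - 1]], u[i], side="right")
    return states


def generate_patient(
    group_params: GroupDynamicsParams,
    stay_hours: float,
    sedation_stop_h: float,
    interval_h: float,
    rng: np.random.Generator,
    *,
    patient_id: str = "P001",
    outcome: Outcome = Outcome.FAVORABLE,
    missingness: float = 0.0,
) -> PatientRecord:
    """Simulate one patient's PS and PR series on the grid t = 0, dt, ... <= stay.

    GOSE at 6 months is drawn uniformly from {5..8} for favorable and {1..4}
    for unfavorable patients — only the dichotomy matters downstream.
    """
    if stay_hours < interval_h:
        raise ValueError("stay must cover at least one sampling interval")
    if sedation_stop_h > stay_hours:
        raise ValueError("sedation_stop must be <= stay")
    times = np.arange(0.0, stay_hours + 0.5 * interval_h, interval_h)
    times = times[times <= stay_hours]
    ps_idx = _sample_chain(group_params.ps_transition, group_params.ps_transition_post,
                           group_params.ps_initial, times, sedation_stop_h, rng)
    pr_idx = _sample_chain(group_params.pr_transition, group_params.pr_transition_post,
                           group_params.pr_initial, times, sedation_stop_h, rng)
    keep = np.ones(len(times), dtype=bool)
    if missingness > 0:
        keep = rng.random(len(times)) >= missingness
        keep[:2] = True  # a record needs >= 2 observations
    obs = [
        PupilObservation(time_h=float(t), ps=PS_STATES[i], pr=PR_STATES[j])
        for t, i, j, k in zip(times, ps_idx, pr_idx, keep)
        if k
    ]
    if outcome is Outcome.FAVORABLE:
        gose = int(rng.integers(5, 9))
    else:
        gose = int(rng.integers(1, 5))
    return PatientRecord(
        patient_id=patient_id,
        observations=obs,
        sedation_stop_h=float(sedation_stop_h),
        discharge_h=float(stay_hours),
        gose_6m=gose,
        outcome=outcome,
    )


def _truncnorm_days(mean: float, sd: float, rng: np.random.Generator, lower: float = 1.0) -> float:
    """One truncated-normal draw (days), truncated below at `lower`."""
    if sd == 0:
        return max(mean, lower)
    while True:
        x = rng.normal(mean, sd)
        if x >= lower:
            return x


def generate_cohort(config: CohortConfig) -> list[PatientRecord]:
    """Generate the full synthetic cohort; reproducible for a fixed seed."""
    rng = np.random.default_rng(config.seed)
    patients: list[PatientRecord] = []
    specs = [(Outcome.FAVORABLE, config.favorable_params)] * config.n_favorable + [
        (Outcome.UNFAVORABLE, config.unfavorable_params)
    ] * config.n_unfavorable
    for k, (outcome, params) in enumerate(specs, start=1):
        stay_d = _truncnorm_days(config.stay_mean_days, config.stay_sd_days, rng)
        sed_d = min(_truncnorm_days(config.sedation_mean_days, config.sedation_sd_days, rng), stay_d)
        # round to whole grid points; sedation stop at least one interval in
        stay_h = max(round(stay_d * 24.0 / config.interval_h), 1) * config.interval_h
        sed_h = min(max(round(sed_d * 24.0 / config.interval_h), 1) * config.interval_h, stay_h)
        patients.append(
            generate_patient(
                params,
                stay_hours=stay_h,
                sedation_stop_h=sed_h,
                interval_h=config.interval_h,
                rng=rng,
                patient_id=f"P{k:03d}",
                outcome=outcome,
                missingness=config.missingness,
            )
        )
    return patients


def stationary_distribution(transition: np.ndarray) -> np.ndarray:
    """Stationary vector of a row-stochastic matrix via eigen-decomposition."""
    m = np.asarray(transition, dtype=float)
    w, v = np.linalg.eig(m.T)
    i = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(v[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()
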