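"""Cohort readers/writers and pipeline configuration.

A cohort on disk is a directory with two CSVs — ``patients.csv``
(patient_id, sedation_stop_h, discharge_h, gose_6m, outcome) and
``observations.csv`` (patient_id, time_h, ps_state, pr_state) — plus a JSON
sidecar ``config.json`` recording the full simulation configuration and seed.
Times are hours since admission; states are the uppercase enum tokens.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd
import yaml

from .cohort import CohortValidationError, Outcome, PatientRecord, PupilObservation
from .indices import JumpDenominator
from .simulate import CohortConfig
from .states import PhotoReactivityState, PupilSizeState

PATIENTS_CSV = "patients.csv"
OBSERVATIONS_CSV = "observations.csv"
CONFIG_JSON = "config.json"


def write_cohort(cohort: list[PatientRecord], out_dir: str | Path,
                 config: CohortConfig | None = None) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            {
                "patient_id": p.patient_id,
                "sedation_stop_h": p.sedation_stop_h,
                "discharge_h": p.discharge_h,
                "gose_6m": p.gose_6m,
                "outcome": p.outcome.value,
            }
            for p in cohort
        ]
    ).to_csv(out / PATIENTS_CSV, index=False)
    pd.DataFrame(
        [
            {
                "patient_id": p.patient_id,
                "time_h": o.time_h,
                "ps_state": o.ps.value,
                "pr_state": o.pr.value,
            }
            for p in cohort
            for o in p.observations
        ]
    ).to_csv(out / OBSERVATIONS_CSV, index=False)
    if config is not None:
        (out / CONFIG_JSON).write_text(json.dumps(config.to_dict(), indent=2))
    return out


def read_cohort(in_dir: str | Path) -> list[PatientRecord]:
    """Load and validate a cohort directory.

    Malformed rows (unknown state tokens, orphan observations, non-monotone
    times, outcome/GOSE inconsistencies) raise CohortValidationError naming
    the offending file, line and value.
    """
    d = Path(in_dir)
    pat_path, obs_path = d / PATIENTS_CSV, d / OBSERVATIONS_CSV
    for p in (pat_path, obs_path):
        if not p.exists():
            raise FileNotFoundError(f"missing {p}")
    patients = pd.read_csv(pat_path)
    observations = pd.read_csv(obs_path)

    errors: list[str] = []
    ps_tokens = {s.value for s in PupilSizeState}
    pr_tokens = {s.value for s in PhotoReactivityState}
    for i, row in observations.iterrows():
        line = i + 2  # header is line 1
        if row["ps_state"] not in ps_tokens:
            errors.append(f"{obs_path.name}:{line}: unknown ps_state token {row['ps_state']!r}")
        if row["pr_state"] not in pr_tokens:
            errors.append(f"{obs_path.name}:{line}: unknown pr_state token {row['pr_state']!r}")
    known_ids = set(patients["patient_id"])
    orphans = set(observations["patient_id"]) - known_ids
    for pid in sorted(orphans):
        errors.append(f"{obs_path.name}: orphan observations for unknown patient {pid!r}")
    if errors:
        raise CohortValidationError("; ".join(errors))

    records = []
    grouped = dict(tuple(observations.groupby("patient_id", sort=False)))
    for i, row in patients.iterrows():
        pid = row["patient_id"]
        if pid not in grouped:
            raise CohortValidationError(f"{pat_path.name}:{i + 2}: patient {pid!r} has no observations")
        g = grouped[pid]
        obs = [
            PupilObservation(float(t), PupilSizeState(ps), PhotoReactivityState(pr))
            for t, ps, pr in zip(g["time_h"], g["ps_state"], g["pr_state"])
        ]
        records.append(
            PatientRecord(
                patient_id=str(pid),
                observations=obs,
                sedation_stop_h=float(row["sedation_stop_h"]),
                discharge_h=float(row["discharge_h"]),
                gose_6m=int(row["gose_6m"]),
                outcome=Outcome(row["outcome"]),
            )
        )
    return records


def read_cohort_config(in_dir: str | Path) -> CohortConfig | None:
    path = Path(in_dir) / CONFIG_JSON
    if not path.exists():
        return None
    return CohortConfig.from_dict(json.loads(path.read_text()))


@dataclasses.dataclass
class PipelineConfig:
    """End-to-end pipeline settings; round-trips losslessly through YAML."""

    out_dir: str = "pupildyn_out"
    seed: int = 0
    jump_denominator: JumpDenominator = "per_measurement"
    roc_mode: str = "in_sample"
    max_nd: int = 10
    cohort: CohortConfig = dataclasses.field(default_factory=CohortConfig)

    def to_dict(self) -> dict:
        return {
            "out_dir": self.out_dir,
            "seed": self.seed,
            "jump_denominator": self.jump_denominator,
            "roc_mode": self.roc_mode,
            "max_nd": self.max_nd,
            "cohort": self.cohort.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "cohort" in d and isinstance(d["cohort"], dict):
            d["cohort"] = CohortConfig.from_dict(d["cohort"])
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
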