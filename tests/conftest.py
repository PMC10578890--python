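import numpy as np
import pytest

from pupildyn.cohort import Outcome, PatientRecord, PupilObservation
from pupildyn.simulate import CohortConfig, generate_cohort
from pupildyn.states import PhotoReactivityState as PR
from pupildyn.states import PupilSizeState as PS


def make_patient(ps_tokens, pr_tokens=None, *, interval=2.0, sedation_stop=None,
                 gose=6, patient_id="T01"):
    """Hand-build a record from state-name sequences on a 2-h grid."""
    ps_seq = [PS[t] for t in ps_tokens]
    pr_seq = [PR[t] for t in (pr_tokens or ["BILATERAL_PRESENT"] * len(ps_seq))]
    assert len(ps_seq) == len(pr_seq)
    obs = [
        PupilObservation(i * interval, a, b)
        for i, (a, b) in enumerate(zip(ps_seq, pr_seq))
    ]
    discharge = obs[-1].time_h
    stop = sedation_stop if sedation_stop is not None else discharge / 2
    return PatientRecord(
        patient_id=patient_id,
        observations=obs,
        sedation_stop_h=stop,
        discharge_h=discharge,
        gose_6m=gose,
    )


@pytest.fixture(scope="session")
def default_cohort():
    """One default 14F+6U synthetic cohort, shared across tests."""
    return generate_cohort(CohortConfig(seed=42))


@pytest.fixture
def rng():
    return np.random.default_rng(2026)
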