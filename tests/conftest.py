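import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ovsurv import CohortSpec, PatientRecord, TreatmentEvent, generate_cohort

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_patient(
    pid="P0",
    events=(),
    label=1,
    age=55.0,
    ca125=900.0,
    ascites="yes",
    grade=3,
    stage="4",
    histology="serous",
    flags=(),
    ecog=2,
):
    """Hand-built patient for unit tests; events given as (symbol, month)."""
    return PatientRecord(
        patient_id=pid,
        age=age,
        ca125=ca125,
        ascites=ascites,
        grade=grade,
        stage=stage,
        histology=histology,
        comorbidity_flags=frozenset(flags),
        ecog=ecog,
        events=tuple(TreatmentEvent(s, m) for s, m in events),
        survived_3yr=label,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A labelled, fully observed cohort of 80 patients."""
    return generate_cohort(CohortSpec(n_patients=80, seed=42))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)
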