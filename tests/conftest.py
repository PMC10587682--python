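import numpy as np
import pytest

from vpapk.cohort import CohortConfig, generate_cohort
from vpapk.data import Covariates, DoseEvent, ObservationEvent, SubjectRecord


@pytest.fixture
def reference_covariates() -> Covariates:
    """A cohort-median-like child: 19 kg, ~5 y, syrup, no co-medication."""
    return Covariates(sex="male", age=4.92, weight=19.0, albumin=42.2,
                      daily_dose=23.44 * 19.0, formulation="syrup")


@pytest.fixture
def steady_state_subject(reference_covariates) -> SubjectRecord:
    """One subject on 240 mg q12h at steady state with two troughs."""
    cov = Covariates(sex="male", age=6.0, weight=20.0, albumin=42.0,
                     daily_dose=480.0, formulation="syrup")
    doses = (DoseEvent(time=0.0, amount=240.0, interdose_interval=12.0,
                       steady_state=True),)
    obs = (ObservationEvent(time=12.0, concentration=55.0, time_after_dose=12.0),
           ObservationEvent(time=24.0, concentration=60.0, time_after_dose=12.0))
    return SubjectRecord(id="S1", covariates=cov, doses=doses, observations=obs)


@pytest.fixture(scope="session")
def small_cohort():
    """100-subject synthetic cohort simulated from the serrano2019 truth."""
    cfg = CohortConfig(n_subjects=100, seed=42)
    ds, sidecar = generate_cohort(cfg, allow_ka_fallback=True)
    return ds, sidecar


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
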