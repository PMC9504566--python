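import numpy as np
import pytest

from shockwatch.cohort import CohortConfig, generate_cohort
from shockwatch.filtering import filter_patient


@pytest.fixture(scope="session")
def small_cohort():
    """Eight patients with default study conditions (kept small for speed)."""
    return generate_cohort(CohortConfig(n_patients=8, seed=7))


@pytest.fixture(scope="session")
def filtered_patient(small_cohort):
    patient = small_cohort[0]
    return patient, filter_patient(patient.ecg, patient.resp)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
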