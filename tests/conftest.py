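import numpy as np
import pytest

from glucosim import CohortSpec, canonical_protocol, sample_cohort
from glucosim.engine import Arm


@pytest.fixture(scope="session")
def template_patient():
    """Deterministic midpoint-template patient with flat diurnal fluxes."""
    cohort = sample_cohort(CohortSpec(n_patients=1, seed=0, cv=0.0,
                                      flux_dispersion=0.0))
    return cohort[0]


@pytest.fixture(scope="session")
def fixture_cohort():
    """The canonical 15-patient synthetic cohort used across the suite."""
    return sample_cohort(CohortSpec(n_patients=15, seed=0))


@pytest.fixture()
def basic_protocol():
    """Canonical 24-h four-meal protocol with all variability off."""
    return canonical_protocol(arm=Arm.OPEN_LOOP, seed=0, variability=False)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
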