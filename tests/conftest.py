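import numpy as np
import pytest

from rootgrav import OrganGeometry, Sensitivities


@pytest.fixture(scope="session")
def cohort_geometry() -> OrganGeometry:
    """Wild-type cohort-mean geometry: r=65 um, Lgz=0.6 mm, vg=0.13 mm/h."""
    return OrganGeometry(radius_r=0.065, growth_zone_Lgz=0.60, tip_velocity_vg=0.13)


@pytest.fixture(scope="session")
def cohort_sensitivities() -> Sensitivities:
    """Cohort-mean sensitivities, horizontal gravistimulation."""
    return Sensitivities(gamma=1.6, eta=1.1, theta0=0.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240101)
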