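import numpy as np
import pytest

from pulsetwin.network import (load_default_network, single_vessel_network)
from pulsetwin.patients import PatientProfile, build_patient, compute_bsa
from pulsetwin.aneurysm import SeverityClass


@pytest.fixture(scope="session")
def default_net():
    return load_default_network()


@pytest.fixture()
def fresh_net():
    return load_default_network()


def reference_profile() -> PatientProfile:
    """A fixed mid-cohort subject used as the reproducible reference."""
    return PatientProfile(
        age_years=55.0, weight_kg=75.0, height_cm=175.0, gender=1,
        bsa_m2=compute_bsa(75.0, 175.0), map_mmhg=92.0,
        ejection_fraction=0.62, cardiac_output_l_min=5.6,
        heart_rate_bpm=60.0)


@pytest.fixture(scope="session")
def reference_patient(default_net):
    """Converged healthy reference subject (one simulation per session)."""
    rng = np.random.default_rng(0)
    return build_patient(reference_profile(), default_net,
                         SeverityClass.healthy, rng, patient_id="ref")


DB_SEED = 101
DB_COUNTS = dict(n_healthy=18, n_aaa_per_class=14)


@pytest.fixture(scope="session")
def acceptance_like_db():
    """The desk-scale study cohort: 18 healthy + 14 per AAA class,
    simulated once per session and shared by cohort-level tests."""
    from pulsetwin.database import generate_database
    from pulsetwin.solver import SolverConfig

    ds, manifest = generate_database(
        DB_COUNTS["n_healthy"], DB_COUNTS["n_aaa_per_class"], seed=DB_SEED,
        solver_config=SolverConfig(periodicity_tol_mmhg=0.2, max_cycles=10))
    return ds, manifest


@pytest.fixture(scope="session")
def small_tube():
    """Short uniform vessel + Windkessel for analytic solver checks."""
    return single_vessel_network(length=0.3, n_elements=30,
                                 R=1.0e8, C=5e-9)
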