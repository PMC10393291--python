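import numpy as np
import pytest

from gradparc.synthetic import SyntheticCohortSpec, icosphere, synth_cohort


@pytest.fixture(scope="session")
def ico0():
    """12-vertex icosahedron (no medial wall)."""
    return icosphere(0)


@pytest.fixture(scope="session")
def ico2():
    """162-vertex icosphere without a medial wall."""
    return icosphere(2)


@pytest.fixture(scope="session")
def ico2_wall():
    """162-vertex icosphere with a 5% polar medial-wall cap."""
    return icosphere(2, medial_cap_frac=0.05)


@pytest.fixture(scope="session")
def ico3_wall():
    return icosphere(3, medial_cap_frac=0.05)


@pytest.fixture(scope="session")
def small_cohort():
    """Aligned desk cohort: s=2 sphere, 8 parcels, 2 networks, 6 subjects."""
    spec = SyntheticCohortSpec(
        mesh_subdivisions=2,
        n_parcels=8,
        n_networks=2,
        n_subjects=6,
        timepoints=120,
        misalignment_deg=0.0,
        phase_encodings=("AP",),
    )
    return synth_cohort(spec, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
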