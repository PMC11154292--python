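import numpy as np
import pytest

from echowall import CohortConfig, WallImageSpec, generate_cohort, generate_wall_image


@pytest.fixture(scope="session")
def default_cohort():
    """Full-size cohort under the default study conditions."""
    return generate_cohort(seed=7)


@pytest.fixture(scope="session")
def plaque_subset(default_cohort):
    return default_cohort[default_cohort["plaque_present"]]


@pytest.fixture()
def small_config():
    """A fast, reduced cohort for unit tests."""
    return CohortConfig(
        n_subjects=400,
        plaque_fraction=0.67,
        n_nuisance=6,
        n_repeat_scans=40,
        seed=11,
    )


@pytest.fixture(scope="session")
def speckled_image():
    """Speckled far-wall fixture with known region medians (10/44/180)."""
    return generate_wall_image(WallImageSpec(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
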