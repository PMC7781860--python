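import numpy as np
import pytest

from esacea.cohort import ArmProfile, generate_cohort
from esacea.config import basecase_config_path, load_config


@pytest.fixture(scope="session")
def basecase():
    return load_config(basecase_config_path())


@pytest.fixture(scope="session")
def small_cohort():
    """Three dozen patients per arm; enough to exercise every downstream path."""
    darbe = ArmProfile("darbepoetin-alfa", 36, 10.68, 0.98, 0.0979, 12319.41)
    epo = ArmProfile("epoetin-beta", 36, 11.63, 0.32, 0.0309, 919.47)
    return generate_cohort(darbe, seed=11) + generate_cohort(epo, seed=12)


def random_stochastic_matrix(rng: np.random.Generator, n: int) -> np.ndarray:
    """Independent test helper: Dirichlet rows give a row-stochastic matrix."""
    return rng.dirichlet(np.ones(n), size=n)
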