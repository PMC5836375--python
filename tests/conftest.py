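import numpy as np
import pytest

from pdeproteome import synthetic_data as synth
from pdeproteome.study_design import make_crossover_design


@pytest.fixture(scope="session")
def truth():
    """Small deterministic proteome shared by read-only tests."""
    return synth.generate_ground_truth(n_proteins=120, plasma_fraction=0.3, seed=11)


@pytest.fixture(scope="session")
def design():
    return make_crossover_design(n_patients=20)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
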