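import numpy as np
import pytest

from vescharge.synthetic import GroundTruth, generate_population

#: titration grids spanning below and above 1/K_B for the two reference
#: membrane compositions
DOPC_LEVELS = [0.05, 0.1, 0.2, 0.5, 1.0, 2.0]
PCPG_LEVELS = [0.1, 0.25, 0.5, 1.0, 2.0, 5.0]

DOPC_TRUTH = dict(n_pg=0.0, k_b_true=4.7, dna_max_true=0.37)
PCPG_TRUTH = dict(n_pg=0.5, k_b_true=0.82, dna_max_true=0.4)


@pytest.fixture(scope="session")
def dopc_population():
    """300 vesicles/level at the zwitterionic reference truth, 30% CV."""
    truth = GroundTruth(**DOPC_TRUTH, cv_vesicle=0.3, seed=42)
    return generate_population(truth, DOPC_LEVELS, 300)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
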