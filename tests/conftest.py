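import numpy as np
import pytest

from bkit.phylo import five_taxon_tree
from bkit.syndata import DemographyScenario, simulate_two_pop_cohort


@pytest.fixture(scope="session")
def const_scenario():
    return DemographyScenario(
        model_id="CONST", ancestral_size=5_000, epoch_params={},
        mutation_rate=1e-8, rate_units="generation",
        sequence_length=1_000_000, sample_sizes=(8, 6))


@pytest.fixture(scope="session")
def const_cohort(const_scenario):
    return simulate_two_pop_cohort(const_scenario, seed=11)


@pytest.fixture(scope="session")
def tree_uniform():
    return five_taxon_tree(branch_length=0.05, omega=0.2)


@pytest.fixture(scope="session")
def tree_cheetah_elevated():
    return five_taxon_tree(branch_length=0.05, omega={"cheetah": 2.0})


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
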