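import pytest

from crosspep.featmatch import ToleranceModel
from crosspep.simulate import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def tolerance():
    return ToleranceModel()


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        seed=11,
        n_case=10,
        n_control=7,
        n_proteins=1,
        protein_length=500,
        planted_fold_changes=(4.0, 0.25),
        planted_protease_weights={"ADAMTS5": 4.0},
        species=("rat", "human"),
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_study(small_config)


@pytest.fixture(scope="session")
def rat_study(small_study):
    return small_study.species_studies["rat"]
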