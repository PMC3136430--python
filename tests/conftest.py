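import numpy as np
import pytest

from gohinge import make_toy_two_state, build_double_well


@pytest.fixture(scope="session")
def toy():
    return make_toy_two_state(seed=1)


@pytest.fixture(scope="session")
def toy_model(toy):
    return build_double_well(
        toy.open_structure, toy.closed_structure,
        ligand_pairs=toy.ligand_contacts,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
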