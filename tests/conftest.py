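import numpy as np
import pytest
from hypothesis import settings

from blockssa import (
    ReactionNetwork,
    Species,
    cyclic_chain,
    random_network,
)
from blockssa.network_model import reaction_from_lists

settings.register_profile("ci", derandomize=True, max_examples=60)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy_network() -> ReactionNetwork:
    """A+B->C, C->A+B, 2A->D with small counts — every reaction type once."""
    species = [
        Species(0, "A", 5),
        Species(1, "B", 4),
        Species(2, "C", 0),
        Species(3, "D", 0),
    ]
    reactions = [
        reaction_from_lists(0, 2, [0, 1], [2], 0.5),
        reaction_from_lists(1, 1, [2], [0, 1], 1.0),
        reaction_from_lists(2, 3, [0, 0], [3], 0.25),
    ]
    return ReactionNetwork(species, reactions)


@pytest.fixture(scope="session")
def chain5() -> ReactionNetwork:
    return cyclic_chain(5)


@pytest.fixture(scope="session")
def random64() -> ReactionNetwork:
    """Random consistent 64x64 network with dependents in [8, 16]."""
    return random_network(64, 64, (8, 16), seed=11)


@pytest.fixture(scope="session")
def random256() -> ReactionNetwork:
    """The accuracy-protocol network family at desk scale."""
    return random_network(256, 256, (8, 16), seed=5)
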