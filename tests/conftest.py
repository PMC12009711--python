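import logging

import pytest

from retrofrag import (EncoderConfig, HybridEncoder, ToyReactionSpec,
                       make_toy_fragment_library, make_toy_reactions)

logging.getLogger("retrofrag").setLevel(logging.ERROR)

# compact encoder for unit tests; the default (3x128) config is exercised by
# the acceptance suite
SMALL = dict(n_layers=2, d_h=32, d_z=16, bond_hidden=16, seed=0)


@pytest.fixture(scope="session")
def small_encoder():
    return HybridEncoder(EncoderConfig(**SMALL))


@pytest.fixture(scope="session")
def toy_library():
    return make_toy_fragment_library()


@pytest.fixture(scope="session")
def toy_reaction_pairs():
    return make_toy_reactions(ToyReactionSpec(n=50, seed=2))


@pytest.fixture(scope="session")
def toy_molecules(toy_reaction_pairs):
    return [r.product for r, _ in toy_reaction_pairs]
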