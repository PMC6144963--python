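import numpy as np
import pytest

from coimeta.primers import DEFAULT_PRIMERS
from coimeta.simulate import build_species_pool, generate_reference_db


@pytest.fixture(scope="session")
def small_pool():
    """12 aquatic species in genera of 4 (plus 2 terrestrial), seeded."""
    return build_species_pool(
        n_species=12, genus_size=4, n_freshwater=1, n_brackish=1,
        n_invaders=3, seed=7,
    )


@pytest.fixture(scope="session")
def small_reference(small_pool):
    records, pool = generate_reference_db(small_pool, 1.0, seed=8)
    return records


@pytest.fixture(scope="session")
def primers():
    return DEFAULT_PRIMERS


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
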