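import numpy as np
import pytest

from frugisim import GeneratorParams, InteractionNetwork, TraitTable, generate_community


@pytest.fixture
def toy_network() -> InteractionNetwork:
    """3 plants x 3 birds, 11 observed events; p2 depends on bird B alone."""
    counts = np.array([[3, 0, 1],
                       [0, 2, 0],
                       [1, 0, 4]])
    return InteractionNetwork("toy", ("p1", "p2", "p3"), ("A", "B", "C"), counts)


@pytest.fixture
def toy_traits() -> TraitTable:
    return TraitTable(
        body_mass={"A": 1.2, "B": 0.1, "C": 0.5},
        bill_width={"A": 20.0, "B": 8.0, "C": 12.0},
        fruit_diameter={"p1": 10.0, "p2": 6.0, "p3": 15.0},
    )


@pytest.fixture
def small_community():
    """A reproducible generated community small enough for exhaustive checks."""
    params = GeneratorParams(n_birds_range=(8, 8), n_plants_range=(10, 10))
    return generate_community(params, np.random.default_rng(42), network_id="fixture")
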