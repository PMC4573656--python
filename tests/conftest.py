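import numpy as np
import pytest

from allocov.equations import TreeRecord, builtin_registry, get_equation
from allocov.synthetic import PopulationSpec, generate_population


@pytest.fixture(scope="session")
def registry():
    return builtin_registry()


@pytest.fixture(scope="session")
def beech():
    return get_equation("beech_1")


@pytest.fixture(scope="session")
def guazuma():
    return get_equation("guazuma_ulmifolia")


@pytest.fixture(scope="session")
def beech_population():
    """A moderate BEECH-like population for recovery tests (seeded once)."""
    eq, _ = get_equation("beech_1")
    spec = PopulationSpec("BEECH", 3000, 35.0, 15.0, 25.0, 7.0,
                          agb_equation=eq, agb_rule="equation-times-uniform-noise",
                          seed=20240917)
    return generate_population(spec)


@pytest.fixture(scope="session")
def guazuma_population():
    spec = PopulationSpec("guazuma_ulmifolia", 600, 12.9, 5.1, 5.5, 2.4,
                          seed=20240918)
    return generate_population(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_trees(dbh, ht=None, species="X"):
    ht = [None] * len(dbh) if ht is None else ht
    return [TreeRecord(species=species, dbh_cm=float(d),
                       ht_m=None if h is None else float(h))
            for d, h in zip(dbh, ht)]
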