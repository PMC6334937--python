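import numpy as np
import pytest

from parchmentid.fixtures import haplogroup_table, membrane_variants
from parchmentid.formats import Reference
from parchmentid.synthetic_data import synthetic_reference


@pytest.fixture(scope="session")
def membranes():
    """Published polymorphism lists of the three parchment membranes."""
    return membrane_variants()


@pytest.fixture(scope="session")
def hg_table():
    return haplogroup_table()


@pytest.fixture(scope="session")
def small_reference() -> Reference:
    """A 6 kb circular mitogenome surrogate used across mapping tests."""
    return synthetic_reference(6_000, seed=101, name="sheep_mt", species_label="sheep")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
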