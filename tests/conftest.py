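import numpy as np
import pytest

from microtax.identify import ReferenceDB, build_refdb
from microtax.simgen import ReferenceFixture, make_refdb


@pytest.fixture(scope="session")
def small_fixture() -> ReferenceFixture:
    """2 genera x 2 species x 2 strains of 100 kb genomes with planted markers."""
    return make_refdb(
        n_genera=2, species_per_genus=2, strains_per_species=2,
        genome_len=100_000, seed=11,
    )


@pytest.fixture(scope="session")
def small_db(small_fixture) -> ReferenceDB:
    return build_refdb(
        small_fixture.assemblies, small_fixture.taxonomy, markers=small_fixture.markers
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])
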