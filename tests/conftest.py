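import pytest

from gutreads.lazaro import LazaroConfig
from gutreads.synthetic import (GutCommunitySpec, make_reference_db,
                                simulate_gut_reads)


@pytest.fixture(scope="session")
def small_db():
    """Four 3-kb annotated references (fast enough for the SW oracle)."""
    return make_reference_db(seed=11, n_species=4, genome_len=3000)


@pytest.fixture(scope="session")
def gut_sample(small_db):
    """A small predator-dominated read mixture with its truth table."""
    spec = GutCommunitySpec(
        seed=7,
        proportions={"Species_00": 0.85, "Species_01": 0.07,
                     "Species_02": 0.05, "Species_03": 0.03},
        n_reads=600,
    )
    reads, truth = simulate_gut_reads(spec, small_db)
    return reads, truth


@pytest.fixture
def default_cfg():
    return LazaroConfig(predator_species="Species_00")
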