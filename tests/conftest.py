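import pytest

from mirselect import (
    MicroRNA,
    SimulationConfig,
    UTRRecord,
    simulate_universe,
)
from mirselect.pipeline import build_pairs

LET7_MATURE = "UGAGGUAGUAGGUUGUAUAGUU"
LET7_SEED = "GAGGUAG"


@pytest.fixture(scope="session")
def let7():
    return MicroRNA(name="let-7a-5p", mature=LET7_MATURE, conservation="animal")


@pytest.fixture()
def toy_utr():
    # contains the let-7 8mer CTACCTCA at positions 3-10
    return UTRRecord("T1", "G1", "AACTACCTCAA")


@pytest.fixture(scope="session")
def universe():
    """A default-sized selected universe (gamma = -10 on derived targets)."""
    return simulate_universe(SimulationConfig(rng_seed=7, frac_unpolarized=0.05))


@pytest.fixture(scope="session")
def universe_pairs(universe):
    sense, background = build_pairs(
        universe.utrs, universe.mirnas, universe.snps, maf_threshold=None
    )
    return sense, background
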