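import numpy as np
import pytest

from ampliswarm.align import DEFAULT_PENALTIES, ScoringSystem, transform_scoring
from ampliswarm.bench import CommunitySpec, generate_chained_community, generate_community
from ampliswarm.io import Amplicon, AmpliconPool

BASES = "ACGT"


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[int(i)] for i in rng.integers(0, 4, size=length))


@pytest.fixture(scope="session")
def default_penalties():
    return DEFAULT_PENALTIES


@pytest.fixture(scope="session")
def chained_pool():
    """Two abundant clouds (1000/500 copies) bridged by abundance-2 amplicons."""
    return generate_chained_community(bridge_abundance=2)


@pytest.fixture(scope="session")
def shallow_valley_pool():
    """Same topology but the bridge is too abundant for a deep valley."""
    return generate_chained_community(bridge_abundance=20)


@pytest.fixture(scope="session")
def small_community():
    """A well-separated even community used across clustering tests."""
    spec = CommunitySpec(
        n_species=6,
        abundance_model="even",
        even_abundance=30,
        template_length=90,
        rng_seed=7,
    )
    return generate_community(spec)


def make_pool(records) -> AmpliconPool:
    """Build a pool from (identifier, sequence, abundance) triples."""
    return AmpliconPool(tuple(Amplicon(i, s, a) for i, s, a in records))
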