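import numpy as np
import pytest

from orfanage import synthetic_data as syn
from orfanage.genome_model import Genome


def random_genome(n: int, seed: int, gc: float = 0.5, id: str = "g") -> Genome:
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = "".join(rng.choice(list("ACGT"), size=n, p=p))
    return Genome(id=id, sequence=seq)


@pytest.fixture(scope="session")
def default_fixture():
    """The full-size study fixture: 196-kb genome, 244 ORFs, 9,540-nt
    dispensable locus."""
    return syn.gen_fixture()


@pytest.fixture(scope="session")
def default_metagenome():
    """Default planted metagenomic screen (seeded)."""
    return syn.gen_metagenome(syn.MetagenomeSpec(seed=3))
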