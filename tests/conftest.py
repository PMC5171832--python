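import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")

BASES = np.array(list("ACGT"))


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(BASES, size=n))


@pytest.fixture
def rng():
    return np.random.default_rng(20261001)


@pytest.fixture
def toy_genome():
    """A 13-nt genome with one forward ORF, from a hand-checkable example."""
    from tcrispri import GenomeRecord, OrfRecord

    return GenomeRecord(id="toy", sequence="AAATGCCCTAAGG"), OrfRecord(
        gene="toy1", start=2, end=12, strand="+"
    )
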