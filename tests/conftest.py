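import numpy as np
import pytest

from ampminer import generate_transcriptome
from ampminer.pipeline import DEFAULT_PLANTS

POOL_SEED = 42
N_DECOYS = 174  # 200 transcripts total with the default plant mix


@pytest.fixture(scope="session")
def synthetic_pool():
    """One seeded 200-transcript pool with 26 planted precursors."""
    records, truth = generate_transcriptome(
        list(DEFAULT_PLANTS), N_DECOYS, seed=POOL_SEED)
    return records, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_protein(rng, n, alphabet="ACDEFGHIKLMNPQRSTVWY"):
    return "".join(alphabet[i] for i in rng.integers(len(alphabet), size=n))


def random_nt(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(4, size=n))
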