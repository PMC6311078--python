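import numpy as np
import pytest

from tridca import AMINO_ACIDS, GAP, Alphabet, EncodedMSA


def make_random_msa(B: int, N: int, q: int, seed: int, with_gap: bool = False) -> EncodedMSA:
    """A uniform-random encoded MSA over the first q canonical symbols."""
    rng = np.random.default_rng(seed)
    data = rng.integers(0, q, size=(B, N))
    if with_gap:
        symbols = tuple(AMINO_ACIDS[: q - 1]) + (GAP,)
    else:
        symbols = tuple(AMINO_ACIDS[:q])
    return EncodedMSA(data, Alphabet(symbols))


@pytest.fixture
def random_msa_factory():
    return make_random_msa


@pytest.fixture
def tiny_msa():
    """B=8, N=4, q=3 — the size class every brute-force oracle covers."""
    return make_random_msa(8, 4, 3, seed=42)
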