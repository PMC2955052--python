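import random

import pytest

from degenprobe.alphabet import IUPAC_SETS

DEGENERATE_SYMBOLS = sorted(IUPAC_SETS)
PLAIN_BASES = "ACGT"


@pytest.fixture
def rng():
    return random.Random(20100923)


def random_degenerate(rng: random.Random, length: int, p_ambiguous: float = 0.3) -> str:
    out = []
    for _ in range(length):
        if rng.random() < p_ambiguous:
            out.append(rng.choice(DEGENERATE_SYMBOLS))
        else:
            out.append(rng.choice(PLAIN_BASES))
    return "".join(out)


def random_dna(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(PLAIN_BASES) for _ in range(length))
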