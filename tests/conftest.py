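import numpy as np
import pytest

from breakscape.core import GenomeSequence


def random_genome(seed: int, lengths={"c1": 10_000, "c2": 8_000}, gc=0.5) -> GenomeSequence:
    rng = np.random.default_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    return GenomeSequence(
        {
            c: bases[rng.choice(4, size=L, p=p)].tobytes().decode()
            for c, L in lengths.items()
        }
    )


@pytest.fixture
def genome_10kb() -> GenomeSequence:
    return random_genome(11)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
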