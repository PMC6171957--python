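import random

import pytest

from compscan.proteome_io import CANONICAL_AA, ProteinRecord


def random_sequence(rng: random.Random, length: int, alphabet: str = CANONICAL_AA) -> str:
    return "".join(rng.choice(alphabet) for _ in range(length))


@pytest.fixture
def rng():
    return random.Random(20260927)


@pytest.fixture
def small_proteome(rng):
    """50 random proteins of mixed lengths, plus edge cases."""
    records = [
        ProteinRecord(f"P{i:03d}", random_sequence(rng, rng.randint(8, 200)))
        for i in range(50)
    ]
    records.append(ProteinRecord("POLYN", "N" * 100))
    return records
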