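import random

import pytest

from mpass.seqio import Proteome, ProteinRecord
from mpass.similarity import ScoringScheme

AA20 = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture(scope="session")
def scoring():
    """One scoring scheme per session so the alignment cache is shared."""
    return ScoringScheme()


def random_protein(rng: random.Random, length: int = 120) -> str:
    return "".join(rng.choice(AA20) for _ in range(length))


def mutate(seq: str, rate: float, rng: random.Random) -> str:
    return "".join(
        rng.choice(AA20.replace(aa, "")) if rng.random() < rate else aa for aa in seq
    )


def make_proteome(
    sample_id: str,
    n: int = 5,
    length: int = 120,
    seed: int = 0,
    coverage: float = 1.0,
) -> Proteome:
    rng = random.Random(seed)
    return Proteome(
        sample_id=sample_id,
        records=[
            ProteinRecord(
                id=f"{sample_id}_g{i}",
                sequence=random_protein(rng, length),
                coverage=coverage,
            )
            for i in range(n)
        ],
    )


def mutated_copy(p: Proteome, sample_id: str, rate: float, seed: int = 0) -> Proteome:
    """Same gene set with every protein mutated at ``rate`` per site."""
    rng = random.Random(seed)
    return Proteome(
        sample_id=sample_id,
        records=[
            ProteinRecord(
                id=r.id.replace(p.sample_id, sample_id),
                sequence=mutate(r.sequence, rate, rng),
                coverage=r.coverage,
            )
            for r in p
        ],
    )
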