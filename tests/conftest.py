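import numpy as np
import pytest

from elemtrace import GenomeRecord, Msa, QueryElement, ScoringScheme

BASES = "ACGT"


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


@pytest.fixture(scope="session")
def scheme() -> ScoringScheme:
    return ScoringScheme()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture
def small_msa() -> Msa:
    return Msa(
        rows=[
            ("query", "ACGTACGTAC"),
            ("s1", "ACGTACGTAC"),
            ("s2", "ACCTACG-AC"),
            ("s3", "ACGTTCGTAC"),
        ]
    )


def make_query(rng: np.random.Generator, length: int, label: str = "q") -> QueryElement:
    return QueryElement(id=label, seq=random_dna(rng, length))


def make_genome_with_insert(
    rng: np.random.Generator, insert: str, total: int, genome_id: str = "g"
) -> tuple[GenomeRecord, int]:
    """Random genome with `insert` written over a random window; returns start."""
    bg = random_dna(rng, total)
    start = int(rng.integers(0, total - len(insert) + 1))
    seq = bg[:start] + insert + bg[start + len(insert) :]
    return GenomeRecord(genome_id=genome_id, contigs=[(f"{genome_id}_chr", seq)]), start
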