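"""Shared fixtures: small deterministic genomes and libraries."""

import numpy as np
import pytest

from tnspore.genome import Genome, InsertionLibrary, find_ta_sites


def random_dna(rng, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_genome(rng):
    """A 8 kb random genome (several hundred TA sites)."""
    return Genome("chr", random_dna(rng, 8000))


@pytest.fixture
def small_index(small_genome):
    return find_ta_sites(small_genome)


def spaced_ta_genome(n_sites: int) -> Genome:
    """Genome 'GTAG' * n: TA sites at 2, 6, 10, ... and nowhere else."""
    return Genome("spaced", "GTAG" * n_sites)


def library_from_vector(index, values, condition="custom") -> InsertionLibrary:
    counts = {int(p): int(v) for p, v in zip(index.positions, values) if v > 0}
    return InsertionLibrary(condition, counts, index.genome_id)
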