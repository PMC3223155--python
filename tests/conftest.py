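import numpy as np
import pytest
from hypothesis import settings

import markovbin as mb

settings.register_profile("suite", derandomize=True)
settings.load_profile("suite")

BASES = "ACGT"


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture(scope="session")
def tiny_db():
    """k=1 database from the worked 'AACG' genome plus a poly-T contrast."""
    return mb.build_database(
        [("g_aacg", ["AACG"]), ("g_polyt", ["TTTTTTTT"])],
        k=1,
        missing_cost=10.0,
        strand_policy="forward",
    )


@pytest.fixture(scope="session")
def benchmark():
    """Standard synthetic benchmark: 20 well-separated genomes, seeded."""
    return mb.make_benchmark(
        n_genomes=20,
        genome_length=100_000,
        order=3,
        concentration=0.1,
        reads_per_genome=50,
        read_lengths=(100, 500, 1000),
        seed=42,
    )


@pytest.fixture(scope="session")
def benchmark_db(benchmark):
    return mb.build_database(benchmark.genome_sets, k=5, taxonomy=benchmark.taxonomy)
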