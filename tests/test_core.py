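"""Model training: transition counting, cost vectors, database assembly."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import markovbin as mb
from markovbin._seq import kmer_index, reverse_complement
from markovbin.errors import (
    DegenerateModelError,
    DuplicateGenomeError,
    InvalidParameterError,
    TaxonomyError,
)

from conftest import random_dna

dna = st.text(alphabet="ACGT", min_size=0, max_size=200)


@pytest.mark.parametrize(
    "seq,k,expected",
    [
        # hand-enumerated sliding 2-mer windows
        ("AACG", 1, {"AA": 1, "AC": 1, "CG": 1}),
        # single-state chain: L-k = 8 windows
        ("AAAAAAAAAA", 2, {"AAA": 8}),
        # windows AN and NC are dropped, downstream CG survives
        ("AANCG", 1, {"AA": 1, "CG": 1}),
        ("", 3, {}),
        ("acgt", 1, {"AC": 1, "CG": 1, "GT": 1}),  # case-insensitive
    ],
)
def test_count_transitions_examples(seq, k, expected):
    tc = mb.count_transitions(seq, k)
    assert tc.counts.shape == (4 ** (k + 1),)
    for kmer, n in expected.items():
        assert tc.counts[kmer_index(kmer)] == n
    assert tc.total == sum(expected.values())


def test_count_transitions_rejects_bad_order():
    with pytest.raises(InvalidParameterError):
        mb.count_transitions("ACGT", 0)
    with pytest.raises(InvalidParameterError):
        mb.count_transitions("ACGT", 9)


@given(seq=dna, k=st.integers(1, 4))
@settings(deadline=None, max_examples=100)
def test_gapfree_window_count(seq, k):
    """A gap-free length-L sequence has exactly max(0, L-k) transitions."""
    tc = mb.count_transitions(seq, k)
    assert tc.total == max(0, len(seq) - k)


def test_build_model_worked_example():
    m = mb.build_model(["AACG"], k=1, missing_cost=10.0, strand_policy="forward")
    assert m.costs[kmer_index("AA")] == pytest.approx(math.log(2), abs=1e-12)
    assert m.costs[kmer_index("AC")] == pytest.approx(math.log(2), abs=1e-12)
    assert m.costs[kmer_index("CG")] == 0.0
    other = np.ones(16, bool)
    other[[kmer_index("AA"), kmer_index("AC"), kmer_index("CG")]] = False
    assert (m.costs[other] == 10.0).all()
    assert m.n_transitions_trained == 3


def test_build_model_single_transition_is_certain():
    m = mb.build_model(["AAAA"], k=1, missing_cost=10.0, strand_policy="forward")
    assert m.costs[kmer_index("AA")] == 0.0
    assert (np.delete(m.costs, kmer_index("AA")) == 10.0).all()


def test_build_model_palindrome_equals_doubled_forward():
    both = mb.build_model(["ACGT"], k=1, strand_policy="both")
    doubled = mb.build_model(["ACGT", "ACGT"], k=1, strand_policy="forward")
    np.testing.assert_array_equal(both.costs, doubled.costs)


def test_build_model_degenerate_input_refused():
    with pytest.raises(DegenerateModelError):
        mb.build_model(["NNNNN"], k=2)
    with pytest.raises(InvalidParameterError):
        mb.build_model([], k=2)


@given(st.integers(0, 2**31 - 1))
@settings(deadline=None, max_examples=25)
def test_normalization_and_scale_invariance(seed):
    """Observed transition probabilities per context sum to 1, and
    duplicating the training data leaves the cost vector unchanged."""
    rng = np.random.default_rng(seed)
    seq = random_dna(rng, int(rng.integers(50, 400)))
    k = int(rng.integers(1, 4))
    m = mb.build_model([seq], k=k, strand_policy="forward")
    grid = np.exp(-m.costs.reshape(4**k, 4))
    counts = mb.count_transitions(seq, k).counts.reshape(4**k, 4)
    for ctx in range(4**k):
        observed = counts[ctx] > 0
        if observed.any():
            assert abs(grid[ctx, observed].sum() - 1.0) <= 1e-9
    m2 = mb.build_model([seq, seq], k=k, strand_policy="forward")
    np.testing.assert_array_equal(m.costs, m2.costs)


def test_strand_symmetry(rng):
    seq = random_dna(rng, 300)
    a = mb.build_model([seq], k=3, strand_policy="both")
    b = mb.build_model([reverse_complement(seq)], k=3, strand_policy="both")
    np.testing.assert_array_equal(a.costs, b.costs)


def test_multi_replicon_pooling(rng):
    """Chromosome + plasmid of one genome train a single pooled model."""
    chrom, plasmid = random_dna(rng, 500), random_dna(rng, 100)
    pooled = mb.build_model([chrom, plasmid], k=2, strand_policy="forward")
    expected = (
        mb.count_transitions(chrom, 2).counts + mb.count_transitions(plasmid, 2).counts
    )
    assert pooled.n_transitions_trained == expected.sum()


class TestBuildDatabase:
    def test_shape_k5(self, rng):
        sets = [(f"g{i}", [random_dna(rng, 2000)]) for i in range(3)]
        db = mb.build_database(sets, k=5)
        assert db.matrix.shape == (3, 4096)

    def test_empty_rejected(self):
        with pytest.raises(InvalidParameterError):
            mb.build_database([], k=2)

    def test_row_order_is_input_order(self, rng):
        sets = [(f"g{i}", [random_dna(rng, 800)]) for i in range(4)]
        db1 = mb.build_database(sets, k=2)
        db2 = mb.build_database(sets[::-1], k=2)
        for gid, _ in sets:
            np.testing.assert_array_equal(
                db1.matrix[db1.row_of(gid)], db2.matrix[db2.row_of(gid)]
            )

    def test_duplicate_genome_id_rejected(self, rng):
        seq = random_dna(rng, 100)
        with pytest.raises(DuplicateGenomeError):
            mb.build_database([("g", [seq]), ("g", [seq])], k=1)

    def test_missing_taxonomy_strict_vs_allowed(self, rng):
        sets = [("gX", [random_dna(rng, 200)])]
        table = mb.LineageTable()  # empty: gX unknown
        with pytest.raises(TaxonomyError):
            mb.build_database(sets, k=1, taxonomy=table)
        db = mb.build_database(sets, k=1, taxonomy=table, allow_missing_taxonomy=True)
        assert db.lineages[0].label("phylum") == "NA"


class TestAddGenome:
    def test_incremental_equals_rebuild(self, rng):
        sets = [(f"g{i}", [random_dna(rng, 1500)]) for i in range(10)]
        db9 = mb.build_database(sets[:9], k=3)
        db10 = mb.add_genome(db9, sets[9][0], sets[9][1])
        scratch = mb.build_database(sets, k=3)
        np.testing.assert_array_equal(db10.matrix, scratch.matrix)
        assert db10.genome_ids == scratch.genome_ids
        assert db10.n_genomes == 10

    def test_duplicate_rejected(self, tiny_db):
        with pytest.raises(DuplicateGenomeError):
            mb.add_genome(tiny_db, "g_aacg", ["ACGT"])
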