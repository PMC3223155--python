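"""Seeded synthetic genomes and read samplers.

Genomes are realizations of random low-order Markov chains: each context's
transition row is drawn from a symmetric Dirichlet, then the chain is walked
from a uniform start context. A small concentration (default 0.1) makes the
rows sparse and genome compositions well separated, emulating a reference
set of distinguishable organisms; a huge concentration approaches an i.i.d.
uniform sequence. Read samplers draw uniform start positions and strands
and apply i.i.d. substitution errors, mirroring an evaluation design in
which a fixed number of fragments is sampled from every replicon of every
test genome. Everything is deterministic given the seed.

The generator's default chain order (3) is deliberately lower than the
classifier's default model order (5), so recovery tests do not assume the
model family matches the data-generating process.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from . import _seq
from .errors import InvalidParameterError
from .taxonomy import Lineage, LineageTable

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

DEFAULT_ORDER = 3
DEFAULT_CONCENTRATION = 0.1


@dataclass(frozen=True)
class SyntheticGenomeSpec:
    """Parameters of one synthetic genome draw."""

    order: int = DEFAULT_ORDER
    length: int = 100_000
    concentration: float = DEFAULT_CONCENTRATION
    seed: int = 0

    def __post_init__(self):
        if self.order < 1:
            raise InvalidParameterError("generator order must be >= 1")
        if self.length <= self.order:
            raise InvalidParameterError("genome length must exceed the chain order")
        if self.concentration <= 0:
            raise InvalidParameterError("Dirichlet concentration must be > 0")


def simulate_genome(spec: SyntheticGenomeSpec) -> str:
    """Sample one genome as a walk of an order-``spec.order`` Markov chain."""
    rng = np.random.default_rng(spec.seed)
    n_ctx = 4**spec.order
    rows = rng.dirichlet(np.full(4, spec.concentration), size=n_ctx)
    cum = np.cumsum(rows, axis=1)
    cum[:, -1] = 1.0  # guard against float drift at the top bin
    start = rng.integers(0, 4, size=spec.order)
    codes = np.empty(spec.length, dtype=np.uint8)
    codes[: spec.order] = start
    ctx = 0
    for c in start:
        ctx = ctx * 4 + int(c)
    mask = n_ctx - 1  # power of 4: modular context update via bitmask
    u = rng.random(spec.length - spec.order)
    for i in range(spec.order, spec.length):
        b = int(np.searchsorted(cum[ctx], u[i - spec.order], side="right"))
        codes[i] = b
        ctx = ((ctx << 2) | b) & mask
    return _BASES[codes].tobytes().decode("ascii")


def sample_reads(
    genome: str,
    read_length: int,
    n: int,
    seed: int,
    error_rate: float = 0.0,
    genome_id: str = "genome",
) -> list[tuple[str, str, str, str]]:
    """Draw ``n`` reads: uniform starts, uniform strand, i.i.d. substitutions.

    Returns ``(read_id, sequence, truth_genome_id, strand)`` tuples with
    strand ``"+"`` or ``"-"`` (minus-strand reads are reverse complemented).
    """
    if read_length > len(genome):
        raise InvalidParameterError(
            f"read_length {read_length} exceeds genome length {len(genome)}"
        )
    if read_length < 1 or n < 0:
        raise InvalidParameterError("read_length must be >= 1 and n >= 0")
    if not (0.0 <= error_rate < 1.0):
        raise InvalidParameterError("error_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    starts = rng.integers(0, len(genome) - read_length + 1, size=n)
    strands = rng.integers(0, 2, size=n)
    out = []
    for j in range(n):
        seq = genome[starts[j] : starts[j] + read_length]
        strand = "+"
        if strands[j]:
            seq = _seq.reverse_complement(seq)
            strand = "-"
        if error_rate > 0.0:
            seq = _mutate(seq, error_rate, rng)
        out.append((f"{genome_id}|r{j:05d}|{strand}", seq, genome_id, strand))
    return out


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    codes = _seq.encode(seq).astype(np.int64)
    hit = rng.random(len(codes)) < rate
    if not hit.any():
        return seq
    # replace with one of the three other bases, uniformly
    shift = rng.integers(1, 4, size=int(hit.sum()))
    codes[hit] = (codes[hit] + shift) % 4
    return _BASES[codes.astype(np.uint8)].tobytes().decode("ascii")


@dataclass
class Benchmark:
    """A fully synthetic classification benchmark with ground truth."""

    genome_sets: list[tuple[str, list[str]]]
    taxonomy: LineageTable
    read_sets: dict[int, list[tuple[str, str, str, str]]]  # read_length -> reads
    truth: dict[str, Lineage]  # read_id -> lineage
    truth_genome: dict[str, str]  # read_id -> source genome_id


def make_benchmark(
    n_genomes: int = 20,
    genome_length: int = 100_000,
    order: int = DEFAULT_ORDER,
    concentration: float = DEFAULT_CONCENTRATION,
    reads_per_genome: int = 50,
    read_lengths: Sequence[int] = (100, 500, 1000),
    seed: int = 42,
    error_rate: float = 0.0,
    out_dir: str | Path | None = None,
) -> Benchmark:
    """Generate genomes, distinct synthetic lineages, read sets and truth.

    Each genome gets its own species/genus/family/order/class; genera are
    grouped into phyla round-robin (about five genera per phylum) so that
    coarser ranks aggregate several genomes. With ``out_dir`` the fixture is
    also written as ``genomes.fasta``, ``lineage.tsv``,
    ``reads_L{len}.fasta`` and ``truth.tsv`` — byte-identical across runs
    with the same seed.
    """
    if n_genomes < 2:
        raise InvalidParameterError("a benchmark needs at least 2 genomes")
    root = np.random.SeedSequence(seed)
    genome_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(n_genomes)]
    read_seed_base = int(root.generate_state(2)[1] % (2**31))

    n_phyla = max(2, n_genomes // 5)
    genome_sets: list[tuple[str, list[str]]] = []
    taxonomy = LineageTable()
    for i in range(n_genomes):
        gid = f"G{i + 1:03d}"
        spec = SyntheticGenomeSpec(order, genome_length, concentration, genome_seeds[i])
        genome_sets.append((gid, [simulate_genome(spec)]))
        taxonomy.add(
            gid,
            Lineage(
                superkingdom="Bacteria",
                phylum=f"Phylum_{i % n_phyla + 1:02d}",
                class_=f"Class_{i + 1:03d}",
                order=f"Order_{i + 1:03d}",
                family=f"Family_{i + 1:03d}",
                genus=f"Genus_{i + 1:03d}",
                species=f"Species_{i + 1:03d}",
            ),
        )

    read_sets: dict[int, list[tuple[str, str, str, str]]] = {}
    truth: dict[str, Lineage] = {}
    truth_genome: dict[str, str] = {}
    for li, length in enumerate(read_lengths):
        reads: list[tuple[str, str, str, str]] = []
        for i, (gid, seqs) in enumerate(genome_sets):
            rseed = (read_seed_base + 1000 * li + i) % (2**31)
            for rid, seq, src, strand in sample_reads(
                seqs[0], length, reads_per_genome, rseed, error_rate, gid
            ):
                rid = f"L{length}|{rid}"
                reads.append((rid, seq, src, strand))
                truth[rid] = taxonomy[gid]
                truth_genome[rid] = gid
        read_sets[length] = reads

    bench = Benchmark(genome_sets, taxonomy, read_sets, truth, truth_genome)
    if out_dir is not None:
        _write_fixture(bench, Path(out_dir))
    return bench


def _write_fixture(bench: Benchmark, out_dir: Path) -> None:
    from . import io_formats

    out_dir.mkdir(parents=True, exist_ok=True)
    io_formats.write_fasta(
        ((gid, seqs[0]) for gid, seqs in bench.genome_sets),
        out_dir / "genomes.fasta",
    )
    from .taxonomy import write_lineage_table

    write_lineage_table(bench.taxonomy, out_dir / "lineage.tsv")
    for length, reads in bench.read_sets.items():
        io_formats.write_fasta(
            ((rid, seq) for rid, seq, _, _ in reads),
            out_dir / f"reads_L{length}.fasta",
        )
    io_formats.write_truth_table(
        bench.truth_genome, bench.truth, out_dir / "truth.tsv"
    )
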