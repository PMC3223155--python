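"""Markov-model training and reference-database assembly.

A genome is summarised by a k-th order Markov model over its (k+1)-mer
transitions: for context ``O_m`` (k bases) and successor base extending to
``O_n``, the transition probability is

    P(O_n | O_m) = F(O_m -> O_n) / F(O_m),

where ``F(O_m -> O_n)`` is the observed transition count and ``F(O_m)`` the
row sum of outgoing counts. Models are stored as negative natural-log cost
vectors of length 4^(k+1); transitions never observed in the genome charge a
flat ``missing_cost`` (default 10). A reference database stacks one cost
row per genome into an N x 4^(k+1) float32 matrix ready for dense scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import _seq
from .errors import (
    DegenerateModelError,
    DuplicateGenomeError,
    InvalidParameterError,
    TaxonomyError,
)
from .taxonomy import Lineage, LineageTable

DEFAULT_K = 5
DEFAULT_MISSING_COST = 10.0
STRAND_POLICIES = ("forward", "both")


@dataclass
class TransitionCounts:
    """Integer (k+1)-mer transition counts for one or more sequences."""

    k: int
    counts: np.ndarray  # int64, length 4^(k+1)

    def __post_init__(self):
        self.k = _seq.check_order(self.k)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (4 ** (self.k + 1),):
            raise InvalidParameterError(
                f"counts must have length 4^{self.k + 1}, got {self.counts.shape}"
            )
        if (self.counts < 0).any():
            raise InvalidParameterError("transition counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def __add__(self, other: "TransitionCounts") -> "TransitionCounts":
        if other.k != self.k:
            raise InvalidParameterError("cannot add counts with different k")
        return TransitionCounts(self.k, self.counts + other.counts)


@dataclass
class GenomeModel:
    """One genome's negative-log transition-cost vector."""

    genome_id: str
    k: int
    costs: np.ndarray  # float64, length 4^(k+1)
    missing_cost: float
    n_transitions_trained: int


@dataclass
class ReferenceDatabase:
    """Stacked model matrix plus genome metadata and lineages.

    ``matrix`` is float32 (the container's storage precision) with one row
    per genome in input order; scoring widens to float64 at use time.
    """

    k: int
    missing_cost: float
    strand_policy: str
    matrix: np.ndarray  # float32, shape (N, 4^(k+1))
    genome_ids: list[str]
    display_names: list[str]
    lineages: list[Lineage]
    _index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if self.strand_policy not in STRAND_POLICIES:
            raise InvalidParameterError(
                f"strand_policy must be one of {STRAND_POLICIES}"
            )
        self.matrix = np.asarray(self.matrix, dtype=np.float32)
        n = self.matrix.shape[0]
        if not (len(self.genome_ids) == len(self.display_names) == len(self.lineages) == n):
            raise InvalidParameterError("genome metadata length mismatch with matrix rows")
        if self.matrix.shape[1] != 4 ** (self.k + 1):
            raise InvalidParameterError("matrix width does not match 4^(k+1)")
        self._index = {}
        for i, gid in enumerate(self.genome_ids):
            if gid in self._index:
                raise DuplicateGenomeError(f"duplicate genome_id {gid!r}")
            self._index[gid] = i

    @property
    def n_genomes(self) -> int:
        return self.matrix.shape[0]

    def row_of(self, genome_id: str) -> int:
        return self._index[genome_id]


def count_transitions(sequence: str, k: int) -> TransitionCounts:
    """Count every valid (k+1)-mer window of ``sequence``.

    Each window of k+1 consecutive A/C/G/T bases adds one to the cell of
    its encoded (k+1)-mer (context = first k bases, successor = last base);
    windows containing any other symbol are skipped without affecting later
    windows. A gap-free sequence of length L yields exactly L-k counts; an
    empty or too-short sequence yields all zeros.
    """
    k = _seq.check_order(k)
    return TransitionCounts(k, _seq.count_vector(sequence, k))


def _costs_from_counts(counts: np.ndarray, k: int, missing_cost: float) -> np.ndarray:
    grid = counts.reshape(4**k, 4).astype(np.float64)
    row = grid.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        prob = grid / row[:, None]
        costs = np.where(grid > 0, -np.log(prob), float(missing_cost))
    # -log(1.0) is -0.0; adding +0.0 maps it to +0.0 so costs are all >= 0
    return (costs + 0.0).reshape(-1)


def build_model(
    sequences: Sequence[str],
    k: int = DEFAULT_K,
    missing_cost: float = DEFAULT_MISSING_COST,
    strand_policy: str = "both",
    genome_id: str = "",
) -> GenomeModel:
    """Train one genome's model from its replicon sequences.

    Counts are pooled across all sequences (chromosomes and plasmids form a
    single model); under ``strand_policy="both"`` each sequence's reverse
    complement contributes as well, making classification orientation
    invariant. Costs are ``-ln`` conditional probabilities; cells with zero
    count get ``missing_cost`` exactly.
    """
    k = _seq.check_order(k)
    if strand_policy not in STRAND_POLICIES:
        raise InvalidParameterError(f"strand_policy must be one of {STRAND_POLICIES}")
    if missing_cost < 0:
        raise InvalidParameterError("missing_cost must be non-negative")
    if not sequences:
        raise InvalidParameterError("build_model needs at least one sequence")
    counts = np.zeros(4 ** (k + 1), dtype=np.int64)
    for seq in sequences:
        counts += _seq.count_vector(seq, k)
        if strand_policy == "both":
            counts += _seq.count_vector(_seq.reverse_complement(seq), k)
    total = int(counts.sum())
    if total == 0:
        raise DegenerateModelError(
            f"genome {genome_id or '<unnamed>'}: no countable (k+1)-mer transition "
            f"at k={k}; model would be all missing_cost"
        )
    costs = _costs_from_counts(counts, k, missing_cost)
    return GenomeModel(
        genome_id=genome_id,
        k=k,
        costs=costs,
        missing_cost=float(missing_cost),
        n_transitions_trained=total,
    )


def build_database(
    genome_sets: Sequence[tuple[str, Sequence[str]]],
    k: int = DEFAULT_K,
    missing_cost: float = DEFAULT_MISSING_COST,
    strand_policy: str = "both",
    taxonomy: LineageTable | None = None,
    allow_missing_taxonomy: bool = False,
    display_names: Sequence[str] | None = None,
) -> ReferenceDatabase:
    """Assemble the reference database; row order equals input order."""
    k = _seq.check_order(k)
    if not genome_sets:
        raise InvalidParameterError("build_database needs at least one genome")
    seen: set[str] = set()
    rows = []
    ids: list[str] = []
    lineages: list[Lineage] = []
    for gid, seqs in genome_sets:
        if gid in seen:
            raise DuplicateGenomeError(f"duplicate genome_id {gid!r}")
        seen.add(gid)
        lineages.append(_resolve_lineage(gid, taxonomy, allow_missing_taxonomy))
        model = build_model(seqs, k, missing_cost, strand_policy, genome_id=gid)
        rows.append(model.costs.astype(np.float32))
        ids.append(gid)
    names = list(display_names) if display_names is not None else list(ids)
    return ReferenceDatabase(
        k=k,
        missing_cost=float(missing_cost),
        strand_policy=strand_policy,
        matrix=np.vstack(rows),
        genome_ids=ids,
        display_names=names,
        lineages=lineages,
    )


def _resolve_lineage(
    gid: str, taxonomy: LineageTable | None, allow_missing: bool
) -> Lineage:
    if taxonomy is not None and gid in taxonomy:
        return taxonomy[gid]
    if allow_missing or taxonomy is None:
        return Lineage()
    raise TaxonomyError(
        f"genome_id {gid!r} has no lineage (pass allow_missing_taxonomy=True "
        "to assign an all-NA lineage)"
    )


def add_genome(
    db: ReferenceDatabase,
    genome_id: str,
    sequences: Sequence[str],
    lineage: Lineage | None = None,
    display_name: str | None = None,
) -> ReferenceDatabase:
    """Append one genome; bit-identical to a from-scratch rebuild.

    The new model is trained with the database's own k, missing_cost and
    strand_policy, so the result equals ``build_database`` over the original
    genomes plus this one appended last.
    """
    if genome_id in db._index:
        raise DuplicateGenomeError(f"genome_id {genome_id!r} already in database")
    model = build_model(
        sequences, db.k, db.missing_cost, db.strand_policy, genome_id=genome_id
    )
    return ReferenceDatabase(
        k=db.k,
        missing_cost=db.missing_cost,
        strand_policy=db.strand_policy,
        matrix=np.vstack([db.matrix, model.costs.astype(np.float32)[None, :]]),
        genome_ids=db.genome_ids + [genome_id],
        display_names=db.display_names + [display_name or genome_id],
        lineages=db.lineages + [lineage if lineage is not None else Lineage()],
    )
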