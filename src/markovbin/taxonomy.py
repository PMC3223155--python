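"""Lineage bookkeeping, rank-level accuracy, and composition profiles.

Every genome carries a fixed seven-rank lineage (superkingdom ... species);
unknown ranks are the literal string ``"NA"``. Accuracy at a rank is the
fraction of reads whose predicted label at that rank exactly matches the
truth label — unclassified reads and ``NA`` labels always count as wrong,
so the denominator is the full read set.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Iterable, Mapping

from .errors import TaxonomyError

RANKS: tuple[str, ...] = (
    "superkingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)

NA = "NA"

UNCLASSIFIED = "UNCLASSIFIED"


@dataclass(frozen=True)
class Lineage:
    """Labels at the seven canonical ranks; opaque, case-sensitive strings."""

    superkingdom: str = NA
    phylum: str = NA
    class_: str = NA
    order: str = NA
    family: str = NA
    genus: str = NA
    species: str = NA

    def label(self, rank: str) -> str:
        if rank not in RANKS:
            raise TaxonomyError(f"unknown rank {rank!r}; expected one of {RANKS}")
        return getattr(self, "class_" if rank == "class" else rank)

    def as_tuple(self) -> tuple[str, ...]:
        return tuple(self.label(r) for r in RANKS)

    @classmethod
    def from_labels(cls, labels: Iterable[str]) -> "Lineage":
        labels = tuple(labels)
        if len(labels) != len(RANKS):
            raise TaxonomyError(
                f"lineage needs {len(RANKS)} labels, got {len(labels)}"
            )
        return cls(*labels)


UNCLASSIFIED_LINEAGE = Lineage()


class LineageTable:
    """Mapping genome_id -> :class:`Lineage` with unique ids."""

    def __init__(self, entries: Mapping[str, Lineage] | None = None):
        self._table: dict[str, Lineage] = {}
        for gid, lin in (entries or {}).items():
            self.add(gid, lin)

    def add(self, genome_id: str, lineage: Lineage) -> None:
        if genome_id in self._table:
            raise TaxonomyError(f"duplicate genome_id {genome_id!r} in lineage table")
        self._table[genome_id] = lineage

    def __contains__(self, genome_id: str) -> bool:
        return genome_id in self._table

    def __getitem__(self, genome_id: str) -> Lineage:
        try:
            return self._table[genome_id]
        except KeyError:
            raise TaxonomyError(f"genome_id {genome_id!r} not in lineage table") from None

    def __len__(self) -> int:
        return len(self._table)

    def items(self):
        return self._table.items()


_HEADER = ("genome_id",) + RANKS


def parse_lineage_table(path) -> LineageTable:
    """Read the tab-separated lineage table.

    Schema: ``genome_id`` followed by the seven rank columns, header row
    required. Malformed rows and duplicate ids are rejected with the
    offending line number.
    """
    table = LineageTable()
    with open(path, "r", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise TaxonomyError(f"{path}: empty lineage table") from None
        header = [h.strip() for h in header]
        if tuple(header) != _HEADER:
            missing = set(_HEADER) - set(header)
            detail = f"missing column(s) {sorted(missing)}" if missing else f"got {header}"
            raise TaxonomyError(
                f"{path}: header must be {list(_HEADER)}; {detail}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != len(_HEADER):
                raise TaxonomyError(
                    f"{path}:{lineno}: expected {len(_HEADER)} columns, got {len(row)}"
                )
            gid = row[0].strip()
            if not gid:
                raise TaxonomyError(f"{path}:{lineno}: empty genome_id")
            try:
                table.add(gid, Lineage.from_labels(c.strip() for c in row[1:]))
            except TaxonomyError as exc:
                raise TaxonomyError(f"{path}:{lineno}: {exc}") from None
    return table


def write_lineage_table(table: LineageTable, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_HEADER)
        for gid, lin in table.items():
            writer.writerow((gid,) + lin.as_tuple())


def accuracy_at_rank(
    assignments, truth: Mapping[str, Lineage], rank: str
) -> float:
    """Fraction of reads predicted correctly at ``rank``.

    ``assignments`` is any iterable of objects with ``read_id`` and
    ``lineage`` attributes (``lineage`` may be None for unclassified reads).
    Every read must have a truth lineage.
    """
    if rank not in RANKS:
        raise TaxonomyError(f"unknown rank {rank!r}; expected one of {RANKS}")
    total = 0
    correct = 0
    for a in assignments:
        total += 1
        if a.read_id not in truth:
            raise TaxonomyError(f"read {a.read_id!r} has no truth lineage")
        true_label = truth[a.read_id].label(rank)
        pred = a.lineage
        if pred is None:
            continue
        pred_label = pred.label(rank)
        if pred_label != NA and pred_label == true_label:
            correct += 1
    if total == 0:
        raise TaxonomyError("no assignments to evaluate")
    return correct / total


def genome_accuracy(assignments, truth_genome: Mapping[str, str]) -> float:
    """Fraction of reads assigned back to their exact source genome."""
    total = 0
    correct = 0
    for a in assignments:
        total += 1
        if a.read_id not in truth_genome:
            raise TaxonomyError(f"read {a.read_id!r} has no truth genome")
        if a.genome_id == truth_genome[a.read_id]:
            correct += 1
    if total == 0:
        raise TaxonomyError("no assignments to evaluate")
    return correct / total


def composition_profile(assignments, rank: str, top_n: int | None = None):
    """Tally reads per label at ``rank``, sorted by count descending.

    Returns ``[(label, read_count, fraction), ...]``; unclassified reads
    appear under the label ``UNCLASSIFIED``. With ``top_n``, labels beyond
    the first ``top_n`` are merged into ``OTHER`` so fractions still sum
    to one.
    """
    if rank not in RANKS:
        raise TaxonomyError(f"unknown rank {rank!r}; expected one of {RANKS}")
    counts: dict[str, int] = {}
    total = 0
    for a in assignments:
        total += 1
        label = UNCLASSIFIED if a.lineage is None else a.lineage.label(rank)
        counts[label] = counts.get(label, 0) + 1
    # sort by count desc, label asc for a deterministic tie order
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    if top_n is not None and len(ordered) > top_n:
        head, tail = ordered[:top_n], ordered[top_n:]
        head.append(("OTHER", sum(c for _, c in tail)))
        ordered = head
    return [(label, c, c / total) for label, c in ordered] if total else []
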