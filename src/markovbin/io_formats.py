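"""Readers and writers shared by all modules.

FASTA parsing goes through Biopython (gzip transparently by extension).
The database container is a small documented binary layout:

    bytes 0-9   magic ``MARKOVBIN`` + one version digit (currently ``1``)
    uint32      k
    float64     missing_cost
    uint8       strand policy (0 = forward, 1 = both)
    uint32      N (genome count)
    uint32      metadata byte length
    bytes       metadata: N UTF-8 lines, tab-delimited
                ``genome_id<TAB>display_name<TAB><7 rank labels>``
    floats      N x 4^(k+1) cost matrix, little-endian float32, row-major

All integers are little-endian. Save followed by load round-trips the
database bit-exactly. All writers are deterministic: fixed float format,
fixed column order, no timestamps.
"""

from __future__ import annotations

import gzip
import logging
import math
import struct
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
from Bio import SeqIO

from .core import ReferenceDatabase
from .errors import DatabaseFormatError, FastaError
from .taxonomy import RANKS, Lineage, UNCLASSIFIED

logger = logging.getLogger("markovbin")

_MAGIC_PREFIX = b"MARKOVBIN"
_VERSION = b"1"
_HEADER_STRUCT = struct.Struct("<IdBII")  # k, missing_cost, strand, N, meta_len
_STRAND_CODE = {"forward": 0, "both": 1}
_STRAND_NAME = {v: k for k, v in _STRAND_CODE.items()}


@dataclass
class FastaRecord:
    id: str
    description: str
    sequence: str


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "r")


def read_fasta(path) -> Iterator[FastaRecord]:
    """Stream records from a (possibly gzipped) multi-FASTA file.

    Record id is the first whitespace-delimited header token; records with
    empty sequences are skipped with a warning; a file yielding no records
    at all raises.
    """
    n = 0
    try:
        with _open_text(path) as fh:
            # pearson variant: tolerates leading blank lines / comments
            for rec in SeqIO.parse(fh, "fasta-pearson"):
                seq = str(rec.seq)
                if not seq:
                    logger.warning("%s: record %r has empty sequence, skipped", path, rec.id)
                    continue
                n += 1
                yield FastaRecord(rec.id, rec.description, seq)
    except (OSError, ValueError) as exc:
        raise FastaError(f"{path}: {exc}") from exc
    if n == 0:
        raise FastaError(f"{path}: no FASTA records found")


def write_fasta(records: Iterable[tuple[str, str]], path, width: int = 70) -> None:
    with open(path, "w", newline="\n") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def save_database(db: ReferenceDatabase, path) -> None:
    meta_lines = []
    for gid, name, lin in zip(db.genome_ids, db.display_names, db.lineages):
        meta_lines.append("\t".join((gid, name) + lin.as_tuple()))
    meta = ("\n".join(meta_lines) + "\n").encode("utf-8")
    matrix = np.ascontiguousarray(db.matrix, dtype="<f4")
    with open(path, "wb") as fh:
        fh.write(_MAGIC_PREFIX + _VERSION)
        fh.write(
            _HEADER_STRUCT.pack(
                db.k,
                db.missing_cost,
                _STRAND_CODE[db.strand_policy],
                db.n_genomes,
                len(meta),
            )
        )
        fh.write(meta)
        fh.write(matrix.tobytes())


def _read_exact(fh, n: int, what: str) -> bytes:
    buf = fh.read(n)
    if len(buf) != n:
        raise DatabaseFormatError(f"truncated database file while reading {what}")
    return buf


def load_database(path) -> ReferenceDatabase:
    """Load a saved database; bit-exact inverse of :func:`save_database`."""
    with open(path, "rb") as fh:
        magic = fh.read(len(_MAGIC_PREFIX) + 1)
        if len(magic) < len(_MAGIC_PREFIX) + 1 or magic[: len(_MAGIC_PREFIX)] != _MAGIC_PREFIX:
            raise DatabaseFormatError(f"{path}: not a markovbin database (bad magic)")
        if magic[len(_MAGIC_PREFIX) :] != _VERSION:
            raise DatabaseFormatError(
                f"{path}: unsupported database version "
                f"{magic[len(_MAGIC_PREFIX):].decode('ascii', 'replace')!r} "
                f"(this build reads version {_VERSION.decode()})"
            )
        k, missing_cost, strand, n, meta_len = _HEADER_STRUCT.unpack(
            _read_exact(fh, _HEADER_STRUCT.size, "header")
        )
        if strand not in _STRAND_NAME:
            raise DatabaseFormatError(f"{path}: unknown strand policy code {strand}")
        meta = _read_exact(fh, meta_len, "genome metadata").decode("utf-8")
        ids, names, lineages = [], [], []
        for line in meta.splitlines():
            fields = line.split("\t")
            if len(fields) != 2 + len(RANKS):
                raise DatabaseFormatError(f"{path}: malformed genome metadata line {line!r}")
            ids.append(fields[0])
            names.append(fields[1])
            lineages.append(Lineage.from_labels(fields[2:]))
        if len(ids) != n:
            raise DatabaseFormatError(
                f"{path}: header claims {n} genomes, metadata has {len(ids)}"
            )
        width = 4 ** (k + 1)
        raw = _read_exact(fh, n * width * 4, "cost matrix")
        extra = fh.read(1)
        if extra:
            raise DatabaseFormatError(f"{path}: trailing bytes after cost matrix")
    matrix = np.frombuffer(raw, dtype="<f4").reshape(n, width)
    return ReferenceDatabase(
        k=int(k),
        missing_cost=float(missing_cost),
        strand_policy=_STRAND_NAME[strand],
        matrix=matrix.copy(),
        genome_ids=ids,
        display_names=names,
        lineages=lineages,
    )


RESULT_COLUMNS = ("read_id", "genome_id", "score", "n_transitions") + RANKS


def write_assignments(assignments, path) -> None:
    """Results TSV, one row per assignment (``--top N`` emits extra rows)."""
    with open(path, "w", newline="\n") as fh:
        fh.write("\t".join(RESULT_COLUMNS) + "\n")
        for a in assignments:
            score = "NA" if math.isnan(a.score) else f"{a.score:.6f}"
            lin = a.lineage.as_tuple() if a.lineage is not None else ("NA",) * len(RANKS)
            fh.write(
                "\t".join(
                    (a.read_id, a.genome_id, score, str(a.n_valid_transitions)) + lin
                )
                + "\n"
            )


@dataclass
class ResultRow:
    """One parsed results-TSV row (duck-types Assignment for evaluation)."""

    read_id: str
    genome_id: str
    score: float
    n_valid_transitions: int
    lineage: Lineage | None


def read_assignments(path) -> list[ResultRow]:
    rows = []
    with open(path, "r") as fh:
        header = fh.readline().rstrip("\r\n").split("\t")
        if tuple(header) != RESULT_COLUMNS:
            raise DatabaseFormatError(f"{path}: unexpected results header {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\r\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) != len(RESULT_COLUMNS):
                raise DatabaseFormatError(f"{path}:{lineno}: malformed results row")
            lineage = None if f[1] == UNCLASSIFIED else Lineage.from_labels(f[4:])
            score = float("nan") if f[2] == "NA" else float(f[2])
            rows.append(ResultRow(f[0], f[1], score, int(f[3]), lineage))
    return rows


def write_truth_table(
    truth_genome: Mapping[str, str], truth: Mapping[str, Lineage], path
) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("\t".join(("read_id", "genome_id") + RANKS) + "\n")
        for rid in truth_genome:
            fh.write(
                "\t".join((rid, truth_genome[rid]) + truth[rid].as_tuple()) + "\n"
            )


def read_truth_table(path) -> tuple[dict[str, str], dict[str, Lineage]]:
    genomes: dict[str, str] = {}
    lineages: dict[str, Lineage] = {}
    with open(path, "r") as fh:
        header = fh.readline().rstrip("\r\n").split("\t")
        if tuple(header) != ("read_id", "genome_id") + RANKS:
            raise DatabaseFormatError(f"{path}: unexpected truth header {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\r\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) != 2 + len(RANKS):
                raise DatabaseFormatError(f"{path}:{lineno}: malformed truth row")
            genomes[f[0]] = f[1]
            lineages[f[0]] = Lineage.from_labels(f[2:])
    return genomes, lineages
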