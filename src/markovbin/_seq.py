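"""Sequence encoding shared by model training and read vectorization.

Bases are coded A=0, C=1, G=2, T=3 (case-insensitive); every other IUPAC
symbol codes to -1 and invalidates any (k+1)-mer window containing it.
A (k+1)-mer is indexed big-endian in base 4: the first k bases are the
context, the last base the successor, so index = context_index * 4 + code.
"""

from __future__ import annotations

import numpy as np

from .errors import InvalidParameterError

_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lower case

_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}
_RC_TABLE = str.maketrans(
    {**_COMPLEMENT, **{k.lower(): v.lower() for k, v in _COMPLEMENT.items()}}
)

MAX_ORDER = 8


def check_order(k: int) -> int:
    if not isinstance(k, (int, np.integer)) or k < 1 or k > MAX_ORDER:
        raise InvalidParameterError(
            f"model order k must be an integer in 1..{MAX_ORDER}, got {k!r}"
        )
    return int(k)


def encode(sequence: str) -> np.ndarray:
    """Return per-base codes (int8; -1 for any non-ACGT symbol)."""
    raw = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    return _CODE[raw]


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_RC_TABLE)[::-1]


def transition_indices(sequence: str, k: int) -> np.ndarray:
    """Encoded indices of every valid (k+1)-mer window of ``sequence``.

    A length-L gap-free sequence has L-k windows; windows containing a
    non-ACGT base are dropped without resetting the scan downstream.
    """
    k = check_order(k)
    codes = encode(sequence)
    n = len(codes) - k
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    idx = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for j in range(k + 1):
        c = codes[j : j + n]
        valid &= c >= 0
        idx = idx * 4 + np.where(c < 0, 0, c).astype(np.int64)
    return idx[valid]


def count_vector(sequence: str, k: int) -> np.ndarray:
    """Transition counts over all 4^(k+1) cells (int64)."""
    idx = transition_indices(sequence, k)
    return np.bincount(idx, minlength=4 ** (k + 1)).astype(np.int64)


def kmer_index(kmer: str) -> int:
    """Encoded index of a literal oligonucleotide (test/debug helper)."""
    codes = encode(kmer)
    if (codes < 0).any():
        raise InvalidParameterError(f"ambiguous base in {kmer!r}")
    out = 0
    for c in codes:
        out = out * 4 + int(c)
    return out
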