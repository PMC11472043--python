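"""Binary encoding of the sgRNA-target DNA interface.

An sgRNA-target pair (two aligned 23-nt sequences, protospacer + PAM) is
represented by a 6 x 23 bit matrix: rows 0-3 are the element-wise OR of the
two one-hot encoded sequences under the fixed channel order (A, T, G, C), and
rows 4-5 are a two-bit mismatch-direction channel that restores the
information the OR discards.  A matched position has one set bit in rows 0-3
and direction ``00``; a mismatched position has two set bits and exactly one
direction bit.  For example ``0011-10`` is the mismatch G->C, ``0011-01`` is
C->G, and ``0100-00`` is the matched T->T.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

SITE_LENGTH = 23

#: Fixed one-hot channel order for rows 0-3.  This order (not alphabetical)
#: is what makes T->T encode as 0100 and {G,C} as 0011 simultaneously.
CHANNEL_ORDER = "ATGC"

_CHANNEL_INDEX = {b: i for i, b in enumerate(CHANNEL_ORDER)}
_VALID_BASES = frozenset("ACGTN")


class InvalidBaseError(ValueError):
    """A sequence contains a character outside A/C/G/T/N."""


class InvalidPairError(ValueError):
    """A sequence pair violates the 23-nt equal-length contract."""


def _normalize_seq(seq: str, name: str) -> str:
    """Uppercase, map RNA U to T, and validate the alphabet."""
    s = seq.upper().replace("U", "T")
    for pos, ch in enumerate(s):
        if ch not in _VALID_BASES:
            raise InvalidBaseError(
                f"invalid base {ch!r} at position {pos} in {name}"
            )
    return s


@dataclass
class SgRNATargetPair:
    """One sgRNA-target interface: aligned 23-nt sequences plus locus.

    Coordinates are 0-based, half-open: the site occupies
    ``[start, start + 23)`` on ``chrom``.  ``read_count`` is the (possibly
    normalized) cleavage read count label, absent at inference time.
    """

    sgrna_seq: str
    target_seq: str
    chrom: str = "."
    start: int = 0
    strand: str = "+"
    read_count: Optional[float] = None
    site_id: Optional[str] = field(default=None)

    def __post_init__(self) -> None:
        self.sgrna_seq = _normalize_seq(self.sgrna_seq, "sgrna_seq")
        self.target_seq = _normalize_seq(self.target_seq, "target_seq")
        if len(self.sgrna_seq) != SITE_LENGTH or len(self.target_seq) != SITE_LENGTH:
            raise InvalidPairError(
                "sgRNA and target sequences must both be exactly "
                f"{SITE_LENGTH} nt, got {len(self.sgrna_seq)} and "
                f"{len(self.target_seq)}"
            )
        if self.strand not in {"+", "-"}:
            raise InvalidPairError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.read_count is not None and self.read_count < 0:
            raise InvalidPairError("read_count must be >= 0")

    @property
    def end(self) -> int:
        return self.start + SITE_LENGTH


@dataclass
class InterfaceEncoding:
    """The 6 x 23 binary interface matrix (rows 0-3 bases, rows 4-5 direction)."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.shape != (6, SITE_LENGTH):
            raise InvalidPairError(
                f"interface matrix must be 6x{SITE_LENGTH}, got {self.matrix.shape}"
            )


def encode_base_pair(sgrna_base: str, target_base: str) -> np.ndarray:
    """Encode one aligned base pair as a 6-bit column.

    Rows 0-3 are the OR of the two one-hot vectors (channel order A, T, G, C).
    For a genuine mismatch exactly one direction bit is set: row 4 when the
    sgRNA base's channel index is smaller than the target base's, row 5
    otherwise.  Matches and any position involving N get direction ``00``;
    N contributes an all-zero one-hot.
    """
    a = _normalize_seq(sgrna_base, "sgrna_base")
    b = _normalize_seq(target_base, "target_base")
    if len(a) != 1 or len(b) != 1:
        raise InvalidPairError("encode_base_pair takes single bases")
    col = np.zeros(6, dtype=np.float64)
    ia = _CHANNEL_INDEX.get(a)
    ib = _CHANNEL_INDEX.get(b)
    if ia is not None:
        col[ia] = 1.0
    if ib is not None:
        col[ib] = 1.0
    if ia is not None and ib is not None and ia != ib:
        col[4 if ia < ib else 5] = 1.0
    return col


# Vectorized lookup table: 5 x 5 -> 6 bits, indexed by (sgrna code, target code)
# with codes A=0, T=1, G=2, C=3, N=4.
_CODE = np.full(256, 4, dtype=np.int8)
for _b, _i in _CHANNEL_INDEX.items():
    _CODE[ord(_b)] = _i
_PAIR_TABLE = np.zeros((5, 5, 6), dtype=np.float64)
for _ia in range(5):
    for _ib in range(5):
        sa = "ATGCN"[_ia]
        sb = "ATGCN"[_ib]
        _PAIR_TABLE[_ia, _ib] = encode_base_pair(sa, sb)


def _seq_codes(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def encode_pair(pair: SgRNATargetPair) -> InterfaceEncoding:
    """Encode a full 23-nt pair: column j = encode_base_pair at position j."""
    ca = _seq_codes(pair.sgrna_seq)
    cb = _seq_codes(pair.target_seq)
    matrix = _PAIR_TABLE[ca, cb].T  # (6, 23)
    return InterfaceEncoding(matrix)


def mismatch_count(pair: SgRNATargetPair) -> int:
    """Number of positions where the bases differ and neither is N."""
    ca = _seq_codes(pair.sgrna_seq)
    cb = _seq_codes(pair.target_seq)
    return int(np.sum((ca != cb) & (ca != 4) & (cb != 4)))
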