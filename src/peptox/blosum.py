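"""BLOSUM62 evolutionary-profile encoding.

Every sequence becomes a fixed-shape grid: one BLOSUM62 substitution-score
row per residue position, truncated/padded to ``max_len`` positions
(default 1002).  Padding rows are all-zero, which no real BLOSUM62 row
is, so real and pad positions stay distinguishable; a 0/1 mask is
returned alongside.  Columns are ordered alphabetically by one-letter
code so downstream weights are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio.Align import substitution_matrices

from .sequence_io import (
    AA_INDEX,
    DEFAULT_MAX_LEN,
    STANDARD_AA,
    SequenceError,
    SequenceRecord,
    truncate_or_pad,
)


@lru_cache(maxsize=1)
def blosum62_table() -> np.ndarray:
    """The standard BLOSUM62 scores as a (20, 20) array, rows/columns in
    alphabetical one-letter-code order."""
    mat = substitution_matrices.load("BLOSUM62")
    table = np.zeros((20, 20))
    for i, a in enumerate(STANDARD_AA):
        for j, b in enumerate(STANDARD_AA):
            table[i, j] = mat[a, b]
    assert np.array_equal(table, table.T) and np.all(np.diag(table) > 0)
    return table


@dataclass
class EncodedSequence:
    """Fixed-shape substitution-score grid plus real/pad mask."""

    id: str
    matrix: np.ndarray  # (max_len, 20)
    mask: np.ndarray  # (max_len,), 1 = real position
    label: int | None = None


def encode_blosum62(record: SequenceRecord, max_len: int = DEFAULT_MAX_LEN) -> EncodedSequence:
    """Encode one record as a (max_len, 20) BLOSUM62 row matrix."""
    table = blosum62_table()
    padded, mask = truncate_or_pad(record, max_len=max_len)
    matrix = np.zeros((max_len, 20))
    for i, ch in enumerate(padded.residues):
        if mask[i] == 0.0:
            break
        if ch not in AA_INDEX:
            raise SequenceError(f"nonstandard residue {ch!r} in record {record.id!r}")
        matrix[i] = table[AA_INDEX[ch]]
    return EncodedSequence(id=record.id, matrix=matrix, mask=mask, label=record.label)


def encode_batch(
    records: list[SequenceRecord], max_len: int = DEFAULT_MAX_LEN
) -> tuple[np.ndarray, np.ndarray]:
    """Stack encodings: returns (B, max_len, 20) matrices and (B, max_len) masks."""
    encoded = [encode_blosum62(r, max_len=max_len) for r in records]
    return np.stack([e.matrix for e in encoded]), np.stack([e.mask for e in encoded])
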