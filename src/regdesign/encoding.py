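"""One-hot encoding of DNA sequences, 4 bits per base.

The conversion rule is fixed: A = {1,0,0,0}, G = {0,1,0,0}, C = {0,0,1,0},
T = {0,0,0,1}. A length-L sequence becomes a binary vector of length 4*L,
base-major (all four bits of base 1, then base 2, ...). This vector is the
input layer of the strength-prediction network, so a 224-nt element maps to
an 896-wide input.
"""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np

#: Bit order within each 4-bit block.
BASE_ORDER = "AGCT"

_BASE_INDEX = {base: i for i, base in enumerate(BASE_ORDER)}


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a DNA sequence into its 4-bit-per-base binary vector.

    Parameters
    ----------
    seq : str
        Non-empty string over {A, C, G, T}; case-insensitive. Ambiguity
        codes (N, R, ...) and gaps are rejected.

    Returns
    -------
    numpy.ndarray
        1-D ``int8`` array of length ``4 * len(seq)``. Block ``i`` is the
        one-hot encoding of base ``i`` in (A, G, C, T) bit order.

    Raises
    ------
    ValueError
        If the sequence is empty or contains a non-ACGT character (the
        error message carries the 1-based position of the first offender).
    """
    if not isinstance(seq, str):
        raise TypeError(f"sequence must be a string, got {type(seq).__name__}")
    if len(seq) == 0:
        raise ValueError("cannot encode an empty sequence")
    seq = seq.upper()
    bits = np.zeros(4 * len(seq), dtype=np.int8)
    for i, base in enumerate(seq):
        idx = _BASE_INDEX.get(base)
        if idx is None:
            raise ValueError(
                f"invalid base {base!r} at position {i + 1}: "
                "only A, C, G, T are encodable"
            )
        bits[4 * i + idx] = 1
    return bits


def encode_library(seqs: Sequence[str]) -> np.ndarray:
    """Encode a batch of equal-length sequences into an n x 4L matrix.

    Row ``i`` equals ``encode_sequence(seqs[i])``; row order is preserved.

    Raises
    ------
    ValueError
        If the batch is empty, or any sequence length differs from the
        first (the offending record index is named).
    """
    seqs = list(seqs)
    if not seqs:
        raise ValueError("cannot encode an empty batch of sequences")
    length = len(seqs[0])
    for i, s in enumerate(seqs):
        if len(s) != length:
            raise ValueError(
                f"sequence #{i + 1} has length {len(s)}, "
                f"expected {length} (all sequences must be equal-length)"
            )
    matrix = np.empty((len(seqs), 4 * length), dtype=np.int8)
    for i, s in enumerate(seqs):
        matrix[i] = encode_sequence(s)
    return matrix


def decode_vector(bits: np.ndarray | Sequence[int]) -> str:
    """Invert :func:`encode_sequence`.

    ``decode_vector(encode_sequence(s)) == s`` for every valid sequence.

    Raises
    ------
    ValueError
        If the length is not a multiple of 4 or any 4-bit block is not
        exactly one-hot.
    """
    bits = np.asarray(bits)
    if bits.ndim != 1:
        raise ValueError(f"expected a 1-D bit vector, got ndim={bits.ndim}")
    if bits.size == 0 or bits.size % 4 != 0:
        raise ValueError(
            f"bit vector length {bits.size} is not a positive multiple of 4"
        )
    blocks = bits.reshape(-1, 4)
    if not np.all(np.isin(blocks, (0, 1))):
        raise ValueError("bit vector contains values other than 0 and 1")
    sums = blocks.sum(axis=1)
    bad = np.nonzero(sums != 1)[0]
    if bad.size:
        raise ValueError(
            f"block {bad[0] + 1} is not one-hot "
            f"(bits {blocks[bad[0]].tolist()})"
        )
    indices = np.argmax(blocks, axis=1)
    return "".join(BASE_ORDER[i] for i in indices)
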