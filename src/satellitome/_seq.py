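"""Low-level nucleotide utilities: encoding, reverse complement, rotations.

Sequences cross module boundaries as plain uppercase ACGT strings; hot
paths (read simulation, k-mer hashing, consensus voting) work on uint8
code matrices with A,C,G,T -> 0,1,2,3.
"""

from __future__ import annotations

import numpy as np

from .errors import InvalidAlphabetError

BASES = "ACGT"
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i
_DECODE = np.frombuffer(BASES.encode(), dtype=np.uint8)

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCATGCA")


def encode(seq: str) -> np.ndarray:
    """Encode an ACGT string as a uint8 code array."""
    arr = _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if arr.size and arr.max() > 3:
        bad = seq[int(np.argmax(arr > 3))]
        raise InvalidAlphabetError(f"non-ACGT character {bad!r} in sequence")
    return arr


def decode(codes: np.ndarray) -> str:
    """Decode a uint8 code array (or matrix row) back to a string."""
    return _DECODE[codes].tobytes().decode()


def decode_rows(mat: np.ndarray) -> list[str]:
    """Decode every row of a 2-D code matrix."""
    flat = _DECODE[mat].tobytes().decode()
    width = mat.shape[1]
    return [flat[i : i + width] for i in range(0, len(flat), width)]


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def revcomp_codes(mat: np.ndarray) -> np.ndarray:
    """Reverse complement along the last axis of a code array."""
    return (3 - mat)[..., ::-1]


def rotate(seq: str, k: int) -> str:
    """Left-rotate ``seq`` by ``k`` positions."""
    if not seq:
        return seq
    k %= len(seq)
    return seq[k:] + seq[:k]


def rotations(seq: str):
    for k in range(len(seq)):
        yield seq[k:] + seq[:k]


def canonical_rotation(seq: str) -> str:
    """Lexicographically smallest rotation over both strands.

    Monomers are defined only up to rotation and strand; this canonical
    form makes deduplication and naming deterministic.
    """
    if not seq:
        raise InvalidAlphabetError("empty sequence has no canonical rotation")
    return min(min(rotations(seq)), min(rotations(revcomp(seq))))


def at_fraction(seq: str) -> float:
    if not seq:
        raise InvalidAlphabetError("empty sequence")
    return (seq.count("A") + seq.count("T")) / len(seq)


def kmer_codes(mat: np.ndarray, k: int) -> np.ndarray:
    """Canonical k-mer codes for each row of a read code matrix.

    Returns an (n_reads, L-k+1) uint64 array where each entry is
    min(forward, reverse-complement) 2-bit packed code. Requires k <= 31.
    """
    if not 1 <= k <= 31:
        raise InvalidAlphabetError(f"k={k} outside supported range 1..31")
    if mat.ndim == 1:
        mat = mat[None, :]
    n, length = mat.shape
    w = length - k + 1
    if w <= 0:
        return np.empty((n, 0), dtype=np.uint64)
    fwd = np.zeros((n, w), dtype=np.uint64)
    rev = np.zeros((n, w), dtype=np.uint64)
    m = mat.astype(np.uint64)
    rc = (3 - m)[:, ::-1]
    for j in range(k):
        shift = np.uint64(2 * (k - 1 - j))
        fwd |= m[:, j : j + w] << shift
        rev |= rc[:, j : j + w] << shift
    rev = rev[:, ::-1]  # align rc k-mer i with forward k-mer i
    return np.minimum(fwd, rev)
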