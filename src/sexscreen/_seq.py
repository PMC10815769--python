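"""Low-level nucleotide encoding and k-mer hashing.

Sequences are held as ``uint8`` code arrays: A=0, C=1, G=2, T=3, anything
else (N, IUPAC ambiguity) = 4.  The 2-bit packing keeps a k-mer of k <= 31
inside one ``uint64``, so exact-seed lookup and canonical k-mer counting
reduce to integer comparisons.
"""

from __future__ import annotations

import numpy as np

# code 4 marks positions that can never participate in an exact k-mer match
INVALID = np.uint8(4)

_ENCODE = np.full(256, INVALID, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
    _ENCODE[_b + 32] = _i  # lower case

_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)


def encode(seq: str | bytes) -> np.ndarray:
    """Encode a nucleotide string to a uint8 code array."""
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    return _ENCODE[np.frombuffer(seq, dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode`; invalid codes render as ``N``."""
    return _DECODE[np.minimum(codes, 4)].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    """Reverse-complement a code array (invalid codes stay invalid)."""
    out = np.where(codes < 4, 3 - codes, codes)
    return out[::-1].copy()


def kmer_hashes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Rolling 2-bit hashes of every length-``k`` window.

    Returns ``(hashes, valid)`` where ``hashes[i]`` packs
    ``codes[i:i+k]`` big-endian into a uint64 and ``valid[i]`` is False
    whenever the window contains an invalid code.  ``k`` must be <= 31.
    """
    if not 1 <= k <= 31:
        raise ValueError(f"k must be in [1, 31], got {k}")
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, np.uint64), np.empty(0, bool)
    c = codes.astype(np.uint64)
    bad = codes >= 4
    h = np.zeros(n, dtype=np.uint64)
    invalid = np.zeros(n, dtype=bool)
    for j in range(k):
        h = (h << np.uint64(2)) | (c[j : j + n] & np.uint64(3))
        invalid |= bad[j : j + n]
    return h, ~invalid


_M2 = np.uint64(0x3333333333333333)
_M4 = np.uint64(0x0F0F0F0F0F0F0F0F)
_M8 = np.uint64(0x00FF00FF00FF00FF)
_M16 = np.uint64(0x0000FFFF0000FFFF)


def revcomp_hashes(hashes: np.ndarray, k: int) -> np.ndarray:
    """Hash of the reverse complement of each k-mer, computed bitwise.

    Complementing a 2-bit base code is XOR with 0b11, so ``~h`` complements
    every base at once; reversing the order of the 2-bit groups then yields
    the reverse complement.
    """
    x = ~hashes
    x = ((x & _M2) << np.uint64(2)) | ((x >> np.uint64(2)) & _M2)
    x = ((x & _M4) << np.uint64(4)) | ((x >> np.uint64(4)) & _M4)
    x = ((x & _M8) << np.uint64(8)) | ((x >> np.uint64(8)) & _M8)
    x = ((x & _M16) << np.uint64(16)) | ((x >> np.uint64(16)) & _M16)
    x = (x << np.uint64(32)) | (x >> np.uint64(32))
    return x >> np.uint64(64 - 2 * k)


def canonical_kmer_hashes(codes: np.ndarray, k: int) -> np.ndarray:
    """Hashes of the canonical (strand-min) form of every valid k-mer."""
    fwd, valid = kmer_hashes(codes, k)
    both = np.minimum(fwd, revcomp_hashes(fwd, k))
    return both[valid]
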