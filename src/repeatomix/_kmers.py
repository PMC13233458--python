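"""Vectorized k-mer encoding helpers shared by the clustering, satellite and LTR stages.

Sequences are encoded as uint8 arrays (A,C,G,T -> 0..3); k-mers (k <= 31) are
packed into uint64 by 2-bit shifts. Non-ACGT characters map to A.
"""

from __future__ import annotations

import numpy as np

_LUT = np.zeros(256, dtype=np.uint8)
_LUT[ord("C")] = 1
_LUT[ord("G")] = 2
_LUT[ord("T")] = 3
_LUT[ord("c")] = 1
_LUT[ord("g")] = 2
_LUT[ord("t")] = 3

_COMP = np.array([3, 2, 1, 0], dtype=np.uint8)

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """DNA string -> uint8 code array."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _LUT[raw]


def decode(codes: np.ndarray) -> str:
    return BASES[codes].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return _COMP[codes[::-1]]


def revcomp(seq: str) -> str:
    return decode(revcomp_codes(encode(seq)))


def kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """All overlapping k-mers of a code array, packed into uint64.

    Returns an array of length len(codes) - k + 1 (empty if shorter than k).
    """
    if k > 31:
        raise ValueError("k must be <= 31")
    n = codes.shape[0] - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    out = np.zeros(n, dtype=np.uint64)
    c64 = codes.astype(np.uint64)
    for i in range(k):
        out <<= np.uint64(2)
        out |= c64[i : i + n]
    return out


def kmer_codes_rc(codes: np.ndarray, k: int) -> np.ndarray:
    """k-mers of the reverse complement, reported in forward coordinates.

    Element i is the k-mer of revcomp(seq) that occupies positions
    [i, i+k) of the forward sequence.
    """
    return kmer_codes(_COMP[codes[::-1]], k)[::-1].copy()
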