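"""Numeric sequence codecs shared by the analysis modules.

Bases are encoded A=0, C=1, G=2, T=3; ``N`` and every IUPAC ambiguity code
collapse to 4 (uncallable).  Code 4 never matches anything in alignment or
index structures.
"""

from __future__ import annotations

import numpy as np

A, C, G, T, N = 0, 1, 2, 3, 4

_ENC = np.full(256, N, dtype=np.uint8)
for i, base in enumerate("ACGT"):
    _ENC[ord(base)] = i
    _ENC[ord(base.lower())] = i
_DEC = np.frombuffer(b"ACGTN", dtype=np.uint8)
_COMP = np.array([T, G, C, A, N], dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string to uint8 codes (ambiguity -> 4)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENC[raw]


def decode(codes: np.ndarray) -> str:
    return _DEC[codes].tobytes().decode("ascii")


def complement(codes: np.ndarray) -> np.ndarray:
    return _COMP[codes]


def revcomp(codes: np.ndarray) -> np.ndarray:
    return _COMP[codes][::-1]


def revcomp_str(seq: str) -> str:
    return decode(revcomp(encode(seq)))


def kmer_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """2-bit-packed k-mers and their start positions; k-mers containing an
    uncallable base are dropped.  Requires k <= 31."""
    if k > 31:
        raise ValueError("k must be <= 31 for 2-bit packing")
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    acc = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for j in range(k):
        window = codes[j:j + n]
        valid &= window < 4
        acc = (acc << 2) | (window & 3).astype(np.int64)
    pos = np.nonzero(valid)[0]
    return acc[pos], pos
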