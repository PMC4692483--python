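"""Low-level nucleotide encoding shared by the scanner and background models.

Bases are coded A=0, C=1, G=2, T=3; anything else (N, IUPAC ambiguity)
becomes 4 and never participates in k-mer matching.  The complement of a
coded base b < 4 is ``3 - b``, which is what makes the GC/AT "flip"
background a one-liner.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
N_CODE = 4

_CODE = np.full(256, N_CODE, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_DECODE = np.array(list(BASES + "N"))

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string to int8 codes (case-insensitive)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    """Decode int8 codes back to an uppercase string (4 -> N)."""
    return "".join(_DECODE[np.asarray(codes, dtype=np.int64)])


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def complement_codes(codes: np.ndarray) -> np.ndarray:
    """Complement coded bases; N (code 4) is preserved."""
    out = 3 - codes
    out[codes == N_CODE] = N_CODE
    return out


def kmer_to_index(kmer: str) -> int:
    """Map a k-mer over ACGT to its base-4 integer index."""
    idx = 0
    for c in encode(kmer):
        if c >= N_CODE:
            raise ValueError(f"k-mer contains non-ACGT base: {kmer!r}")
        idx = idx * 4 + int(c)
    return idx


def index_to_kmer(idx: int, width: int) -> str:
    out = []
    for _ in range(width):
        out.append(BASES[idx & 3])
        idx >>= 2
    return "".join(reversed(out))


def window_indices(codes: np.ndarray, width: int) -> tuple[np.ndarray, np.ndarray]:
    """Base-4 index of every length-`width` window plus a validity mask.

    Windows containing any non-ACGT base are flagged invalid; their index
    value is meaningless and must not be used.
    """
    n = len(codes) - width + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    idx = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    clipped = np.where(codes >= N_CODE, 0, codes).astype(np.int64)
    for j in range(width):
        idx = idx * 4 + clipped[j : j + n]
        valid &= codes[j : j + n] < N_CODE
    return idx, valid


def rc_index_table(width: int) -> np.ndarray:
    """Table mapping each base-4 k-mer index to its reverse complement's index."""
    idx = np.arange(4**width, dtype=np.int64)
    rc = np.zeros_like(idx)
    tmp = idx.copy()
    for _ in range(width):
        rc = rc * 4 + (3 - (tmp & 3))
        tmp >>= 2
    return rc


def gc_fraction(seq: str) -> float:
    """Fraction of G+C among ACGT bases of `seq` (N excluded from both counts)."""
    codes = encode(seq)
    acgt = codes < N_CODE
    n = int(acgt.sum())
    if n == 0:
        raise ValueError("sequence has no ACGT bases")
    gc = int(((codes == 1) | (codes == 2)).sum())
    return gc / n
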