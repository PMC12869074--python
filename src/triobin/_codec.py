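"""2-bit k-mer codec shared by the counting and evaluation stages.

k-mers over {A,C,G,T} are packed into uint64 codes, two bits per base
(A=0, C=1, G=2, T=3), most significant bits first.  Because the 2-bit
base order matches ASCII order, sorting codes numerically sorts the
decoded k-mers lexicographically, so a numeric sort doubles as the
lexicographic sort used for text dumps.

All window extraction is vectorised: a length-L sequence yields its
L-k+1 window codes in k shift-or passes over a uint8 base array rather
than per-window Python slicing.
"""
from __future__ import annotations

import numpy as np

#: largest k that fits a uint64 code (2 bits/base)
MAX_K = 31

_BASE_TO_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_TO_CODE[ord(_b)] = _i
    _BASE_TO_CODE[ord(_b.lower())] = _i
_CODE_TO_BASE = np.frombuffer(b"ACGT", dtype=np.uint8)

INVALID = np.uint8(255)


def encode_bases(seq: str | bytes | np.ndarray) -> np.ndarray:
    """Sequence -> uint8 base codes; non-ACGT positions become 255."""
    if isinstance(seq, np.ndarray):
        if seq.dtype == np.uint8:
            return seq
        seq = "".join(seq.tolist())
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    buf = np.frombuffer(seq, dtype=np.uint8)
    return _BASE_TO_CODE[buf]


def decode_bases(codes: np.ndarray) -> str:
    """uint8 base codes -> ACGT string (codes must be valid)."""
    return _CODE_TO_BASE[codes].tobytes().decode("ascii")


def encode_kmer(kmer: str) -> int:
    """Pack a single k-mer string into its uint64 code."""
    b = encode_bases(kmer)
    if (b == INVALID).any():
        raise ValueError(f"non-ACGT character in k-mer {kmer!r}")
    code = 0
    for v in b:
        code = (code << 2) | int(v)
    return code


def decode_kmer(code: int, k: int) -> str:
    """Unpack a uint64 code back into its k-mer string."""
    out = bytearray(k)
    for j in range(k - 1, -1, -1):
        out[j] = _CODE_TO_BASE[code & 3]
        code >>= 2
    return out.decode("ascii")


def revcomp_code(codes: np.ndarray | int, k: int) -> np.ndarray | int:
    """Reverse-complement of packed k-mer code(s)."""
    scalar = np.isscalar(codes) or isinstance(codes, int)
    c = np.atleast_1d(np.asarray(codes, dtype=np.uint64))
    rc = np.zeros_like(c)
    for _ in range(k):
        rc = (rc << np.uint64(2)) | (np.uint64(3) - (c & np.uint64(3)))
        c = c >> np.uint64(2)
    return int(rc[0]) if scalar else rc


def canonical_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Element-wise lexicographic min of code and its reverse complement."""
    return np.minimum(codes, revcomp_code(codes, k))


def window_codes(
    seq: str | np.ndarray, k: int, canonical: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """All valid k-window codes of ``seq`` and their 0-based start positions.

    Windows containing any non-ACGT base are dropped (the surrounding
    windows are unaffected).  Returns ``(codes, starts)`` where both are
    1-D arrays of equal length; codes are canonical if requested.
    """
    b = encode_bases(seq)
    n = b.size - k + 1
    if n <= 0:
        return np.empty(0, np.uint64), np.empty(0, np.int64)
    valid = b != INVALID
    bb = np.where(valid, b, 0).astype(np.uint64)

    fwd = np.zeros(n, np.uint64)
    for j in range(k):
        fwd |= bb[j : j + n] << np.uint64(2 * (k - 1 - j))
    if canonical:
        cb = np.uint64(3) - bb
        rc = np.zeros(n, np.uint64)
        for j in range(k):
            rc |= cb[j : j + n] << np.uint64(2 * j)
        codes = np.minimum(fwd, rc)
    else:
        codes = fwd

    cs = np.concatenate(([0], np.cumsum(valid)))
    ok = (cs[k:] - cs[:-k]) == k
    starts = np.flatnonzero(ok).astype(np.int64)
    return codes[ok], starts


def codes_to_base_matrix(codes: np.ndarray, k: int) -> np.ndarray:
    """(M,) packed codes -> (M, k) uint8 base-code matrix."""
    codes = np.asarray(codes, dtype=np.uint64)
    out = np.empty((codes.size, k), dtype=np.uint8)
    for j in range(k):
        out[:, j] = (codes >> np.uint64(2 * (k - 1 - j))) & np.uint64(3)
    return out
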