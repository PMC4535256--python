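"""2-bit k-mer packing and Hamming-distance primitives shared by the
uniqueness filter and the read genotyper.

A k-mer (k <= 32) packs into one uint64, two bits per base.  The Hamming
distance between two packed k-mers is the popcount of
``((x ^ y) | ((x ^ y) >> 1)) & 0b0101...01`` — one set bit per differing base.
"""

from __future__ import annotations

import numpy as np

_ENCODE_TABLE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE_TABLE[ord(_b)] = _i
    _ENCODE_TABLE[ord(_b.lower())] = _i


def encode(seq: str) -> np.ndarray:
    """Encode an ACGT string as a uint8 array in 0..3; 255 marks N/other."""
    return _ENCODE_TABLE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def pack(arr: np.ndarray) -> int:
    """Pack a 0..3 uint8 array (length <= 32) into a single integer code."""
    code = 0
    for b in arr:
        code = (code << 2) | int(b)
    return code


def pack_seq(seq: str) -> int:
    arr = encode(seq)
    if (arr == 255).any():
        raise ValueError(f"cannot pack sequence containing non-ACGT base: {seq!r}")
    return pack(arr)


def window_codes(arr: np.ndarray, k: int) -> np.ndarray:
    """Packed codes of every length-k window of *arr* (uint64, len = n-k+1).

    Windows touching a non-ACGT base get the sentinel ``2**63`` so they can
    never equal (or lie within Hamming distance k of) a real primer code.
    """
    n = len(arr)
    if n < k:
        return np.empty(0, dtype=np.uint64)
    bad = arr == 255
    a = np.where(bad, 0, arr).astype(np.uint64)
    codes = np.zeros(n - k + 1, dtype=np.uint64)
    for j in range(k):
        codes = (codes << np.uint64(2)) | a[j : n - k + 1 + j]
    if bad.any():
        bad_window = (
            np.convolve(bad.astype(np.int64), np.ones(k, dtype=np.int64), "valid") > 0
        )
        codes[bad_window] = np.uint64(1) << np.uint64(63)
    return codes


def base_mask(k: int) -> np.uint64:
    """Alternating 01 mask selecting one bit per base position."""
    m = 0
    for _ in range(k):
        m = (m << 2) | 1
    return np.uint64(m)


def hamming_counts(codes: np.ndarray, query: int, k: int) -> np.ndarray:
    """Per-window base mismatch counts between packed *codes* and *query*.

    Windows flagged with the bit-63 sentinel (they overlap a non-ACGT base)
    are reported at distance >= k+1 so no tolerance can accept them.
    """
    x = codes ^ np.uint64(query)
    y = (x | (x >> np.uint64(1))) & base_mask(k)
    counts = np.bitwise_count(y).astype(np.int64)
    counts += ((codes >> np.uint64(63)) & np.uint64(1)).astype(np.int64) * (k + 1)
    return counts
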