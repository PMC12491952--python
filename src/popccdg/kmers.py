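"""Low-level canonical k-mer machinery.

K-mers up to k=31 are packed 2 bits per base into uint64 (A=00, C=01,
G=10, T=11) so that counting, canonicalization and de Bruijn adjacency
are vectorizable with numpy.  Longer k-mers (the sketching default is
k=51) are handled as byte strings.

The canonical form of a k-mer is the lexicographic minimum of the k-mer
and its reverse complement; for the packed representation the 2-bit
encoding is order-preserving, so the numeric minimum coincides with the
lexicographic one.  Windows containing a non-ACGT symbol are skipped
(the symbol breaks the k-mer window, it is never substituted).
"""

from __future__ import annotations

import numpy as np

MAX_PACKED_K = 31

# base -> 2-bit code; 4 marks anything that is not A/C/G/T
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[ord(chr(_b).lower())] = _i

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def seq_to_codes(seq: str | bytes) -> np.ndarray:
    """Map a sequence to an array of 2-bit codes (4 for non-ACGT)."""
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    return _CODE[np.frombuffer(seq, dtype=np.uint8)]


def revcomp_str(seq: str) -> str:
    return "".join(_COMPLEMENT.get(b, "N") for b in reversed(seq.upper()))


def canonical_str(kmer: str) -> str:
    rc = revcomp_str(kmer)
    return kmer if kmer <= rc else rc


def revcomp64(x: np.ndarray | int, k: int) -> np.ndarray | int:
    """Reverse complement of packed k-mers, vectorized bit-twiddling."""
    x = np.bitwise_not(np.asarray(x, dtype=np.uint64))
    x = ((x >> np.uint64(2)) & np.uint64(0x3333333333333333)) | (
        (x & np.uint64(0x3333333333333333)) << np.uint64(2)
    )
    x = ((x >> np.uint64(4)) & np.uint64(0x0F0F0F0F0F0F0F0F)) | (
        (x & np.uint64(0x0F0F0F0F0F0F0F0F)) << np.uint64(4)
    )
    x = x.byteswap()
    return x >> np.uint64(64 - 2 * k)


def pack_kmer(kmer: str) -> int:
    """Pack a single k-mer string (ACGT only, len <= 31) into uint64."""
    codes = seq_to_codes(kmer)
    if (codes > 3).any():
        raise ValueError(f"non-ACGT symbol in k-mer {kmer!r}")
    v = np.uint64(0)
    for c in codes:
        v = (v << np.uint64(2)) | np.uint64(c)
    return int(v)


def unpack_kmer(x: int, k: int) -> str:
    out = []
    for shift in range(2 * (k - 1), -2, -2):
        out.append("ACGT"[(int(x) >> shift) & 3])
    return "".join(out)


def _forward_encodings(codes: np.ndarray, k: int) -> np.ndarray:
    """Packed forward encodings of every valid k-window of `codes`."""
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    bad = (codes > 3).astype(np.int32)
    # window is valid iff it spans no bad symbol
    cbad = np.concatenate([[0], np.cumsum(bad)])
    valid = (cbad[k:] - cbad[:-k]) == 0
    clean = (codes & np.uint8(3)).astype(np.uint64)
    out = np.zeros(n, dtype=np.uint64)
    for j in range(k):  # k shift-or passes instead of a windowed dot
        out <<= np.uint64(2)
        out |= clean[j : j + n]
    return out[valid]


def canonical_kmers_packed(seq: str | bytes, k: int) -> np.ndarray:
    """All canonical packed k-mers of a sequence, in positional order."""
    fwd = _forward_encodings(seq_to_codes(seq), k)
    if fwd.size == 0:
        return fwd
    return np.minimum(fwd, revcomp64(fwd, k))


def canonical_kmers_str(seq: str, k: int) -> list[str]:
    """Canonical k-mer strings of a sequence (any k), positional order."""
    seq = seq.upper()
    out = []
    last_bad = -1
    for i, ch in enumerate(seq):
        if ch not in "ACGT":
            last_bad = i
        if i >= k - 1 and last_bad <= i - k:
            out.append(canonical_str(seq[i - k + 1 : i + 1]))
    return out


def aggregate_counts(kmers: np.ndarray, weights: np.ndarray | None = None):
    """Sum weights per distinct k-mer; returns (sorted unique, totals)."""
    if kmers.size == 0:
        return kmers, np.empty(0, dtype=np.int64)
    uniq, inv = np.unique(kmers, return_inverse=True)
    if weights is None:
        weights = np.ones(kmers.size, dtype=np.int64)
    totals = np.bincount(inv, weights=weights).astype(np.int64)
    return uniq, totals
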