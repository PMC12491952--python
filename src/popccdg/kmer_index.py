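"""Per-sample k-mer counting and the multi-sample population count index.

This is the desk-scale stand-in for a counting colored de Bruijn graph:
a table of canonical k-mers with one count column per sample, after
error filtering (minimum count) and unitig count smoothing.  One index
is built per partition of samples; genotyping queries it for the counts
of allele-specific k-mers across every sample at once.
"""

from __future__ import annotations

import io
import json
import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from . import kmers as km
from .errors import (
    ConfigurationError,
    EstimationError,
    InputIOError,
    ValidationError,
)

FORMAT_VERSION = 1
MAGIC = "POPCCDG"

DEFAULT_K = 31
DEFAULT_MIN_COUNT = 3  # drops singletons and doubletons (likely errors)
DEFAULT_CAP_FACTOR = 3.0  # count ceiling = ceil(cap_factor * depth)


@dataclass
class KmerCountTable:
    """Canonical k-mer -> count for one sample.

    ``kmers`` is sorted; uint64-packed for k <= 31, byte strings above.
    """

    k: int
    sample_id: str
    kmers: np.ndarray
    counts: np.ndarray

    def __len__(self) -> int:
        return int(self.kmers.size)

    @property
    def packed(self) -> bool:
        return self.kmers.dtype == np.uint64

    def as_dict(self) -> dict[str, int]:
        if self.packed:
            return {
                km.unpack_kmer(x, self.k): int(c)
                for x, c in zip(self.kmers, self.counts)
            }
        return {
            x.decode("ascii"): int(c) for x, c in zip(self.kmers, self.counts)
        }


@dataclass
class SampleMeta:
    sample_id: str
    depth: float | None = None  # expected count of a diploid two-copy k-mer
    sex_call: str = "unknown"
    partition_id: int = 0


def _validate_k(k: int) -> None:
    if not isinstance(k, (int, np.integer)) or k <= 1 or k > 63 or k % 2 == 0:
        raise ConfigurationError(f"k must be odd and in (1, 63], got {k}")


def _iter_sequences(reads) -> Iterable[str]:
    """Yield sequences from an iterable of strings or a FASTA/FASTQ path."""
    if isinstance(reads, (str, os.PathLike)):
        import pysam

        path = os.fspath(reads)
        if not os.path.exists(path):
            raise InputIOError(f"cannot read sequence file: {path}")
        with pysam.FastxFile(path) as fh:
            for rec in fh:
                if rec.sequence:
                    yield rec.sequence
    else:
        for seq in reads:
            yield str(seq)


def count_kmers(
    reads,
    k: int = DEFAULT_K,
    min_count: int = DEFAULT_MIN_COUNT,
    sample_id: str = "sample",
) -> KmerCountTable:
    """Count canonical k-mers of a read set, dropping rare ones.

    ``reads`` may be an iterable of sequences or a path to a
    FASTA/FASTQ file (optionally gzipped).  K-mer windows spanning a
    non-ACGT symbol are skipped.  Counts below ``min_count`` are
    removed (default 3: singletons and doubletons are almost always
    sequencing errors).
    """
    _validate_k(k)
    if min_count < 1:
        raise ConfigurationError(f"min_count must be >= 1, got {min_count}")

    if k <= km.MAX_PACKED_K:
        parts_k: list[np.ndarray] = []
        parts_c: list[np.ndarray] = []
        batch: list[str] = []
        batch_len = 0

        def flush():
            nonlocal batch_len
            if not batch:
                return
            # join reads with 'N' so windows never straddle two reads
            arr = km.canonical_kmers_packed("N".join(batch), k)
            if arr.size:
                u, c = km.aggregate_counts(arr)
                parts_k.append(u)
                parts_c.append(c)
            batch.clear()
            batch_len = 0

        for seq in _iter_sequences(reads):
            batch.append(str(seq))
            batch_len += len(seq) + 1
            if batch_len >= (1 << 23):
                flush()
        flush()
        if not parts_k:
            kk = np.empty(0, dtype=np.uint64)
            cc = np.empty(0, dtype=np.int64)
        else:
            kk, cc = km.aggregate_counts(
                np.concatenate(parts_k),
                np.concatenate(parts_c),
            )
    else:
        from collections import Counter

        counter: Counter[str] = Counter()
        for seq in _iter_sequences(reads):
            counter.update(km.canonical_kmers_str(seq, k))
        items = sorted(counter.items())
        kk = np.array([s for s, _ in items], dtype=f"S{k}")
        cc = np.array([c for _, c in items], dtype=np.int64)

    keep = cc >= min_count
    return KmerCountTable(k=k, sample_id=sample_id, kmers=kk[keep], counts=cc[keep])


# ---------------------------------------------------------------------------
# unitig smoothing


def _unitig_labels_packed(keys: np.ndarray, k: int) -> np.ndarray:
    """Label each canonical k-mer with its unitig (maximal non-branching
    path) in the de Bruijn graph induced by the key set.

    Each node has two sides: R (extending the canonical string to the
    right) and L (extending its reverse complement to the right, i.e.
    the left side of the canonical string).  Two nodes are merged iff
    the edge between them is the unique edge on both touched sides.
    """
    n = keys.size
    if n == 0:
        return np.empty(0, dtype=np.int64)
    mask = np.uint64((1 << (2 * k)) - 1)
    rc = km.revcomp64(keys, k)

    def extensions(orient: np.ndarray):
        """For each node, 4 candidate successors of an orientation.

        Returns (neighbor_index, present, entered_left_side) with shape
        (n, 4); neighbor_index is into ``keys``.
        """
        base = (orient << np.uint64(2)) & mask
        cand = base[:, None] | np.arange(4, dtype=np.uint64)[None, :]
        cand_rc = km.revcomp64(cand, k)
        canon = np.minimum(cand, cand_rc)
        idx = np.searchsorted(keys, canon)
        idx_c = np.clip(idx, 0, n - 1)
        present = keys[idx_c] == canon
        entered_left = cand == canon  # read neighbor forward -> left side
        return idx_c, present, entered_left

    idxR, presR, leftR = extensions(keys)  # right side of canonical string
    idxL, presL, leftL = extensions(rc)  # left side (via reverse complement)

    degR = presR.sum(axis=1)
    degL = presL.sum(axis=1)

    edges_u: list[np.ndarray] = []
    edges_v: list[np.ndarray] = []
    for idx, pres, left, deg in ((idxR, presR, leftR, degR), (idxL, presL, leftL, degL)):
        unique_side = deg == 1
        if not unique_side.any():
            continue
        col = pres[unique_side].argmax(axis=1)
        rows = np.flatnonzero(unique_side)
        nb = idx[rows, col]
        nb_left = left[rows, col]
        # neighbor's touched side must also have degree 1
        nb_deg = np.where(nb_left, degL[nb], degR[nb])
        ok = (nb_deg == 1) & (nb != rows)  # self-loops never merge
        edges_u.append(rows[ok])
        edges_v.append(nb[ok])

    if edges_u:
        u = np.concatenate(edges_u)
        v = np.concatenate(edges_v)
    else:
        u = v = np.empty(0, dtype=np.int64)
    graph = coo_matrix((np.ones(u.size, dtype=np.int8), (u, v)), shape=(n, n))
    _, labels = connected_components(graph, directed=False)
    return labels


def _unitig_labels_str(keys: Sequence[bytes], k: int) -> np.ndarray:
    """Dict-based unitig labelling for the long-k (unpacked) path."""
    strs = [s.decode("ascii") for s in keys]
    pos = {s: i for i, s in enumerate(strs)}
    n = len(strs)

    def side_info(i: int, orient: str):
        found = []
        for b in "ACGT":
            cand = orient[1:] + b
            canon = km.canonical_str(cand)
            j = pos.get(canon)
            if j is not None:
                found.append((j, cand == canon))
        return found

    degL = np.zeros(n, dtype=np.int64)
    degR = np.zeros(n, dtype=np.int64)
    nbrR: list = [None] * n
    nbrL: list = [None] * n
    for i, s in enumerate(strs):
        r = side_info(i, s)
        l = side_info(i, km.revcomp_str(s))
        degR[i] = len(r)
        degL[i] = len(l)
        nbrR[i] = r[0] if len(r) == 1 else None
        nbrL[i] = l[0] if len(l) == 1 else None

    u_list, v_list = [], []
    for i in range(n):
        for nbr in (nbrR[i], nbrL[i]):
            if nbr is None:
                continue
            j, entered_left = nbr
            if j == i:
                continue
            if (degL[j] if entered_left else degR[j]) == 1:
                u_list.append(i)
                v_list.append(j)
    graph = coo_matrix(
        (np.ones(len(u_list), dtype=np.int8), (u_list, v_list)), shape=(n, n)
    )
    _, labels = connected_components(graph, directed=False)
    return labels


def smooth_by_unitig(table: KmerCountTable) -> KmerCountTable:
    """Replace every k-mer count by the mean count along its unitig.

    The key set is partitioned into maximal non-branching paths of the
    induced de Bruijn graph; each member count becomes the rounded
    (nearest integer, ties to even) arithmetic mean of its path.  The
    key set is unchanged.  Smoothing compresses per-sample count
    information dramatically at a nominal accuracy cost, which is why
    it is the only preprocessing enabled by default.
    """
    if len(table) == 0:
        return KmerCountTable(table.k, table.sample_id, table.kmers, table.counts)
    if table.packed:
        labels = _unitig_labels_packed(table.kmers, table.k)
    else:
        labels = _unitig_labels_str(table.kmers, table.k)
    sums = np.bincount(labels, weights=table.counts.astype(np.float64))
    sizes = np.bincount(labels)
    means = np.rint(sums / sizes).astype(np.int64)
    return KmerCountTable(table.k, table.sample_id, table.kmers, means[labels])


def n_unitigs(table: KmerCountTable) -> int:
    """Number of maximal non-branching paths over the table's key set."""
    if len(table) == 0:
        return 0
    if table.packed:
        labels = _unitig_labels_packed(table.kmers, table.k)
    else:
        labels = _unitig_labels_str(table.kmers, table.k)
    return int(labels.max()) + 1


def estimate_depth(table: KmerCountTable, min_count: int = DEFAULT_MIN_COUNT) -> float:
    """Modal smoothed count, restricted to [min_count, 4 * median].

    The mode of the count histogram over that window estimates the
    expected count of a diploid two-copy k-mer (the lambda of the
    emission model).  When the restricted histogram is flat the median
    is returned instead.
    """
    if len(table) == 0:
        raise EstimationError("cannot estimate depth from an empty table")
    counts = table.counts
    med = float(np.median(counts))
    hi = max(int(4 * med), min_count)
    window = counts[(counts >= min_count) & (counts <= hi)]
    if window.size == 0:
        return med
    values, freqs = np.unique(window, return_counts=True)
    if np.unique(freqs).size == 1 and values.size > 1:
        return med
    return float(values[freqs.argmax()])


# ---------------------------------------------------------------------------
# population index


@dataclass
class PopulationIndex:
    """K-mer -> per-sample count matrix for one partition of samples."""

    k: int
    samples: list[SampleMeta]
    kmers: np.ndarray  # sorted
    counts: np.ndarray  # (n_kmers, n_samples) uint16
    format_version: int = FORMAT_VERSION
    min_count: int = DEFAULT_MIN_COUNT  # count filter applied at build time

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def sample_index(self, sample_id: str) -> int:
        for i, s in enumerate(self.samples):
            if s.sample_id == sample_id:
                return i
        raise ValidationError(f"unknown sample: {sample_id!r}")

    def depths(self) -> np.ndarray:
        return np.array([s.depth for s in self.samples], dtype=np.float64)

    def lookup(self, packed: np.ndarray) -> np.ndarray:
        """Count matrix rows for canonical packed k-mers (0 if absent)."""
        out = np.zeros((packed.size, len(self.samples)), dtype=np.int64)
        if self.kmers.size == 0 or packed.size == 0:
            return out
        idx = np.searchsorted(self.kmers, packed)
        idx_c = np.clip(idx, 0, self.kmers.size - 1)
        hit = self.kmers[idx_c] == packed
        out[hit] = self.counts[idx_c[hit]]
        return out

    def header(self) -> dict:
        return {
            "magic": MAGIC,
            "format_version": self.format_version,
            "k": self.k,
            "min_count": self.min_count,
            "n_kmers": int(self.kmers.size),
            "samples": [
                {
                    "sample_id": s.sample_id,
                    "depth": s.depth,
                    "sex_call": s.sex_call,
                    "partition_id": s.partition_id,
                }
                for s in self.samples
            ],
        }


def build_index(
    tables: Sequence[KmerCountTable],
    metas: Sequence[SampleMeta] | None = None,
    cap_factor: float = DEFAULT_CAP_FACTOR,
    min_count: int = DEFAULT_MIN_COUNT,
) -> PopulationIndex:
    """Merge per-sample count tables into one population index.

    The key set is the union over samples; absent counts are stored as
    zero.  Per-sample counts are capped at ceil(cap_factor * depth) to
    bound repeat-induced blowup, and the per-sample depth is estimated
    and stored when the supplied metadata has none.
    """
    if not tables:
        raise ValidationError("no tables to merge")
    ks = {t.k for t in tables}
    if len(ks) != 1:
        raise ConfigurationError(f"mixed k across tables: {sorted(ks)}")
    k = ks.pop()
    if metas is None:
        metas = [SampleMeta(sample_id=t.sample_id) for t in tables]
    if len(metas) != len(tables):
        raise ValidationError("one SampleMeta per table required")
    ids = [m.sample_id for m in metas]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"duplicate sample ids: {ids}")

    keys = np.unique(np.concatenate([t.kmers for t in tables]))
    counts = np.zeros((keys.size, len(tables)), dtype=np.uint16)
    out_metas = []
    for j, (t, m) in enumerate(zip(tables, metas)):
        depth = m.depth
        if depth is None:
            depth = estimate_depth(t, min_count=min_count) if len(t) else 1.0
        cap = max(1, math.ceil(cap_factor * depth))
        idx = np.searchsorted(keys, t.kmers)
        counts[idx, j] = np.minimum(t.counts, min(cap, 65535)).astype(np.uint16)
        out_metas.append(
            SampleMeta(m.sample_id, float(depth), m.sex_call, m.partition_id)
        )
    return PopulationIndex(
        k=k, samples=out_metas, kmers=keys, counts=counts, min_count=min_count
    )


def query_counts(index: PopulationIndex, sequence: str) -> np.ndarray:
    """Per-sample counts for every constituent canonical k-mer.

    Returns an (n_kmers, n_samples) array in sequence-position order;
    rows of zeros for k-mers absent from all samples.
    """
    if len(sequence) < index.k:
        raise ValidationError(
            f"query of length {len(sequence)} shorter than k={index.k}"
        )
    if index.kmers.dtype == np.uint64:
        packed = km.canonical_kmers_packed(sequence, index.k)
        return index.lookup(packed)
    strs = km.canonical_kmers_str(sequence, index.k)
    arr = np.array(strs, dtype=index.kmers.dtype)
    out = np.zeros((arr.size, len(index.samples)), dtype=np.int64)
    if arr.size:
        idx = np.searchsorted(index.kmers, arr)
        idx_c = np.clip(idx, 0, index.kmers.size - 1)
        hit = index.kmers[idx_c] == arr
        out[hit] = index.counts[idx_c[hit]]
    return out


# ---------------------------------------------------------------------------
# serialization: versioned text container (JSON header + sorted records)


def save_index(index: PopulationIndex, path: str) -> None:
    with io.open(path, "w", newline="\n") as fh:
        fh.write(json.dumps(index.header(), sort_keys=True) + "\n")
        packed = index.kmers.dtype == np.uint64
        for i in range(index.kmers.size):
            kmer = (
                km.unpack_kmer(index.kmers[i], index.k)
                if packed
                else index.kmers[i].decode("ascii")
            )
            fh.write(kmer + "\t" + " ".join(map(str, index.counts[i])) + "\n")


def load_index(path: str) -> PopulationIndex:
    if not os.path.exists(path):
        raise InputIOError(f"cannot read index file: {path}")
    with io.open(path) as fh:
        try:
            header = json.loads(fh.readline())
        except json.JSONDecodeError as e:
            raise InputIOError(f"malformed index header in {path}: {e}") from e
        if header.get("magic") != MAGIC:
            raise InputIOError(f"not a popccdg index: {path}")
        k = int(header["k"])
        samples = [
            SampleMeta(
                s["sample_id"], s["depth"], s["sex_call"], s["partition_id"]
            )
            for s in header["samples"]
        ]
        kmer_list: list[str] = []
        rows: list[list[int]] = []
        for line in fh:
            kmer, _, rest = line.rstrip("\n").partition("\t")
            kmer_list.append(kmer)
            rows.append([int(x) for x in rest.split()])
        if k <= km.MAX_PACKED_K:
            keys = np.array([km.pack_kmer(s) for s in kmer_list], dtype=np.uint64)
        else:
            keys = np.array(kmer_list, dtype=f"S{k}")
        counts = (
            np.array(rows, dtype=np.uint16)
            if rows
            else np.zeros((0, len(samples)), dtype=np.uint16)
        )
    return PopulationIndex(
        k=k,
        samples=samples,
        kmers=keys,
        counts=counts,
        format_version=int(header["format_version"]),
        min_count=int(header.get("min_count", DEFAULT_MIN_COUNT)),
    )
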