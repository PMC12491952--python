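"""Fractional min-hash sketches for alignment-free QC and partitioning.

A sketch keeps every canonical k-mer whose 64-bit hash falls below
2**64 / scale, so on average one hash is retained per `scale` distinct
k-mers.  Sketches support containment (coverage breadth, chrY-based
sex inference) and drive hierarchical partitioning of a cohort into
groups of closely related samples; subtracting the chrY sketch first
removes the dominant sex-driven signal from the clustering.

The hash is blake2b with an 8-byte digest over the canonical k-mer
bytes, version-pinned so sketches are comparable across runs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import average, to_tree
from scipy.spatial.distance import squareform

from . import kmers as km
from .errors import ComparabilityError, ValidationError
from .kmer_index import _iter_sequences

DEFAULT_SKETCH_K = 51
DEFAULT_SCALE = 10_000

HASH_VERSION = 1  # blake2b(digest_size=8), little-endian


def hash_kmer(kmer: str) -> int:
    return int.from_bytes(
        hashlib.blake2b(kmer.encode("ascii"), digest_size=8).digest(), "little"
    )


@dataclass
class Sketch:
    k: int
    scale: int
    hashes: np.ndarray  # sorted uint64
    abundances: np.ndarray | None = None  # aligned to hashes, >= 1
    name: str = ""

    def __len__(self) -> int:
        return int(self.hashes.size)

    def copy(self, name: str | None = None) -> "Sketch":
        return Sketch(
            self.k,
            self.scale,
            self.hashes.copy(),
            None if self.abundances is None else self.abundances.copy(),
            self.name if name is None else name,
        )


def _check_comparable(a: Sketch, b: Sketch) -> None:
    if a.k != b.k or a.scale != b.scale:
        raise ComparabilityError(
            f"sketches not comparable: k={a.k}/{b.k}, scale={a.scale}/{b.scale}"
        )


def build_sketch(
    sequences,
    k: int = DEFAULT_SKETCH_K,
    scale: int = DEFAULT_SCALE,
    with_abundance: bool = False,
    name: str = "",
) -> Sketch:
    """Sketch a sequence collection or FASTA/FASTQ path.

    Deterministic for the pinned hash; order-independent over input
    records.  ``scale=1`` retains every distinct canonical k-mer hash.
    """
    if scale < 1:
        raise ValidationError(f"scale must be >= 1, got {scale}")
    threshold = (1 << 64) // scale
    counts: dict[int, int] = {}
    for seq in _iter_sequences(sequences):
        for kmer in km.canonical_kmers_str(seq, k):
            h = hash_kmer(kmer)
            if h < threshold:
                counts[h] = counts.get(h, 0) + 1
    hashes = np.array(sorted(counts), dtype=np.uint64)
    abund = (
        np.array([counts[int(h)] for h in hashes], dtype=np.int64)
        if with_abundance
        else None
    )
    return Sketch(k=k, scale=scale, hashes=hashes, abundances=abund, name=name)


def containment(a: Sketch, b: Sketch) -> float:
    """|hashes(a) ∩ hashes(b)| / |hashes(a)|."""
    _check_comparable(a, b)
    if len(a) == 0:
        raise ValidationError("containment of an empty sketch is undefined")
    inter = np.intersect1d(a.hashes, b.hashes, assume_unique=True)
    return inter.size / len(a)


def subtract(a: Sketch, b: Sketch) -> Sketch:
    """Hashes of ``a`` not present in ``b``; abundances preserved."""
    _check_comparable(a, b)
    keep = ~np.isin(a.hashes, b.hashes, assume_unique=True)
    return Sketch(
        a.k,
        a.scale,
        a.hashes[keep],
        None if a.abundances is None else a.abundances[keep],
        a.name,
    )


@dataclass
class QCReport:
    coverage_breadth: float
    depth_estimate: float
    chry_containment: float
    sex_call: str


# chrY containment thresholds: midpoints far from the observed cohort
# means for males (~0.65) and females (~0.08); in between is flagged
# ambiguous rather than silently assigned.
DEFAULT_MALE_THRESHOLD = 0.30
DEFAULT_FEMALE_CEILING = 0.20


def qc_sample(
    sample: Sketch,
    reference: Sketch,
    chry: Sketch,
    male_threshold: float = DEFAULT_MALE_THRESHOLD,
    female_ceiling: float = DEFAULT_FEMALE_CEILING,
) -> QCReport:
    """Coverage breadth, depth estimate, and chrY-based sex inference."""
    if len(reference) == 0:
        raise ValidationError("QC requires a non-empty reference sketch")
    _check_comparable(sample, reference)
    _check_comparable(sample, chry)
    breadth = (
        np.isin(reference.hashes, sample.hashes, assume_unique=True).sum()
        / len(reference)
    )
    if sample.abundances is not None and len(sample):
        shared = np.isin(sample.hashes, reference.hashes, assume_unique=True)
        depth = (
            float(sample.abundances[shared].mean()) if shared.any() else 0.0
        )
    else:
        depth = 0.0
    chry_cont = (
        float(np.isin(chry.hashes, sample.hashes, assume_unique=True).sum() / len(chry))
        if len(chry)
        else 0.0
    )
    if chry_cont > male_threshold:
        sex = "male"
    elif chry_cont < female_ceiling:
        sex = "female"
    else:
        sex = "ambiguous"
    return QCReport(
        coverage_breadth=float(breadth),
        depth_estimate=depth,
        chry_containment=chry_cont,
        sex_call=sex,
    )


# ---------------------------------------------------------------------------
# partitioning


def _distance_matrix(sketches: list[Sketch]) -> np.ndarray:
    """1 - max-containment, robust to unequal sketch sizes."""
    n = len(sketches)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if len(sketches[i]) == 0 or len(sketches[j]) == 0:
                c = 0.0
            else:
                c = max(
                    containment(sketches[i], sketches[j]),
                    containment(sketches[j], sketches[i]),
                )
            d[i, j] = d[j, i] = 1.0 - c
    return d


def _cut_tree(node, min_size: int, max_size: int, partitions: list[list[int]]):
    """Greedy top-down cut: emit a cluster once it fits under max_size."""
    if node.get_count() <= max_size:
        partitions.append(sorted(node.pre_order(lambda leaf: leaf.id)))
        return
    _cut_tree(node.get_left(), min_size, max_size, partitions)
    _cut_tree(node.get_right(), min_size, max_size, partitions)


def partition_cohort(
    sketches: list[Sketch],
    chry: Sketch | None = None,
    min_size: int = 100,
    max_size: int = 350,
    return_linkage: bool = False,
):
    """Partition a cohort into size-bounded groups of related samples.

    chrY hashes are subtracted from every sketch first, the pairwise
    distance is 1 - max-containment, and the average-linkage dendrogram
    is cut greedily top-down so every partition has at most ``max_size``
    members; undersized leftovers are merged into the nearest partition
    (by average distance).  Deterministic for a fixed input order.
    """
    if len(sketches) < 2:
        raise ValidationError("need at least 2 sketches to partition")
    if min_size > max_size:
        raise ValidationError("min_size must be <= max_size")
    if chry is not None and len(chry):
        sketches = [subtract(s, chry) for s in sketches]
    n = len(sketches)
    if n < min_size:
        result = [list(range(n))]
        return (result, None) if return_linkage else result
    dist = _distance_matrix(sketches)
    link = average(squareform(dist, checks=False))
    tree = to_tree(link)
    partitions: list[list[int]] = []
    _cut_tree(tree, min_size, max_size, partitions)
    # merge undersized partitions into their nearest partition
    merged = True
    while merged and len(partitions) > 1:
        merged = False
        for i, part in enumerate(partitions):
            if len(part) >= min_size:
                continue
            best, best_d = None, np.inf
            for j, other in enumerate(partitions):
                if j == i or len(part) + len(other) > max_size:
                    continue
                dd = dist[np.ix_(part, other)].mean()
                if dd < best_d:
                    best, best_d = j, dd
            if best is None:  # no mergeable neighbor under the size cap
                continue
            partitions[best] = sorted(partitions[best] + part)
            partitions.pop(i)
            merged = True
            break
    partitions.sort(key=lambda p: p[0])
    return (partitions, link) if return_linkage else partitions


def linkage_to_newick(link: np.ndarray, names: list[str]) -> str:
    """Newick export of a scipy linkage for external visualization."""
    tree = to_tree(link)

    def render(node) -> str:
        if node.is_leaf():
            return names[node.id]
        left, right = node.get_left(), node.get_right()
        lb = node.dist - left.dist
        rb = node.dist - right.dist
        return f"({render(left)}:{lb:.6f},{render(right)}:{rb:.6f})"

    return render(tree) + ";"


# ---------------------------------------------------------------------------
# JSON container


def save_sketch(sketch: Sketch, path: str) -> None:
    doc = {
        "name": sketch.name,
        "k": sketch.k,
        "scale": sketch.scale,
        "hash_version": HASH_VERSION,
        "hashes": [int(h) for h in sketch.hashes],
        "abundances": (
            None
            if sketch.abundances is None
            else [int(a) for a in sketch.abundances]
        ),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)
        fh.write("\n")


def load_sketch(path: str) -> Sketch:
    with open(path) as fh:
        doc = json.load(fh)
    return Sketch(
        k=int(doc["k"]),
        scale=int(doc["scale"]),
        hashes=np.array(doc["hashes"], dtype=np.uint64),
        abundances=(
            None
            if doc.get("abundances") is None
            else np.array(doc["abundances"], dtype=np.int64)
        ),
        name=doc.get("name", ""),
    )
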