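"""Independent brute-force oracles used by the test suite.

Everything here is written naively (string scanning, exhaustive
enumeration, exact factorials) and independently of the package's
vectorized implementations.
"""

from __future__ import annotations

import math
from collections import Counter

import numpy as np

COMP = str.maketrans("ACGT", "TGCA")


def rc(s: str) -> str:
    return s.translate(COMP)[::-1]


def canon(s: str) -> str:
    r = rc(s)
    return s if s <= r else r


def naive_count_kmers(reads, k: int, min_count: int = 1) -> dict[str, int]:
    counts: Counter[str] = Counter()
    for seq in reads:
        seq = seq.upper()
        for i in range(len(seq) - k + 1):
            w = seq[i : i + k]
            if any(c not in "ACGT" for c in w):
                continue
            counts[canon(w)] += 1
    return {s: c for s, c in counts.items() if c >= min_count}


def naive_unitigs(kmers: set[str], k: int) -> list[set[str]]:
    """Maximal non-branching paths of the induced de Bruijn graph.

    Bidirected convention: every canonical k-mer has a right side
    (extensions of its canonical string) and a left side (extensions of
    its reverse complement); two nodes belong to the same unitig iff
    they are joined by an edge that is unique on both touched sides.
    Components of those edges are returned (brute-force BFS).
    """

    def side_neighbors(node: str, orient: str):
        out = []
        for b in "ACGT":
            cand = orient[1:] + b
            c = canon(cand)
            if c in kmers:
                out.append((c, cand == c))  # (neighbor, entered left side)
        return out

    right = {s: side_neighbors(s, s) for s in kmers}
    left = {s: side_neighbors(s, rc(s)) for s in kmers}
    adj: dict[str, set[str]] = {s: set() for s in kmers}
    for s in kmers:
        for nbrs in (right[s], left[s]):
            if len(nbrs) != 1:
                continue
            t, entered_left = nbrs[0]
            if t == s:
                continue
            t_side = left[t] if entered_left else right[t]
            if len(t_side) == 1:
                adj[s].add(t)
                adj[t].add(s)
    seen: set[str] = set()
    comps = []
    for s in kmers:
        if s in seen:
            continue
        comp = {s}
        stack = [s]
        seen.add(s)
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if v not in seen:
                    seen.add(v)
                    comp.add(v)
                    stack.append(v)
        comps.append(comp)
    return comps


def naive_unique_allele_kmers(
    reference: str,
    allele_seqs: list[list[str]],
    edit_spans: list[tuple[int, int]],
    k: int,
    flank: int,
) -> list[list[set[str]]]:
    """Census-based unique k-mer assignment, brute force.

    ``allele_seqs[l]`` are the flanked allele sequences of locus l
    (reference allele first); ``edit_spans[l]`` is the (start, end)
    of the allele within its flanked sequence, in local coordinates
    shared by all alleles of the locus up to allele length.
    """
    census: Counter[str] = Counter()
    for i in range(len(reference) - k + 1):
        w = reference[i : i + k]
        if all(c in "ACGT" for c in w):
            census[canon(w)] += 1
    for per_locus in allele_seqs:
        for alt in per_locus[1:]:
            for i in range(len(alt) - k + 1):
                census[canon(alt[i : i + k])] += 1
    assigned: Counter[str] = Counter()
    raw: list[list[set[str]]] = []
    for per_locus, (edit_start, _) in zip(allele_seqs, edit_spans):
        per_allele = []
        for seq in per_locus:
            kept = set()
            # allele length differs per allele; edit start is shared
            for i in range(len(seq) - k + 1):
                w = canon(seq[i : i + k])
                if census[w] != 1:
                    continue
                kept.add(w)
            per_allele.append(kept)
        raw.append(per_allele)
        for s in per_allele:
            for w in s:
                assigned[w] += 1
    return [
        [{w for w in s if assigned[w] == 1} for s in per_locus]
        for per_locus in raw
    ]


def exact_hwe(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact HWE p-value by exhaustive enumeration with integer math."""
    n = n_AA + n_Aa + n_aa
    n_A = 2 * n_AA + n_Aa
    n_a = 2 * n_aa + n_Aa

    def weight(h: int):
        aa2 = min(n_A, n_a) - h
        if aa2 < 0 or aa2 % 2:
            return None
        aa = aa2 // 2
        AA = n - aa - h
        if AA < 0:
            return None
        return (
            math.factorial(n)
            * 2**h
            // (math.factorial(AA) * math.factorial(h) * math.factorial(aa))
        )

    weights = {}
    for h in range(min(n_A, n_a) + 1):
        w = weight(h)
        if w is not None:
            weights[h] = w
    total = sum(weights.values())
    obs = weights[n_Aa]
    return sum(w for w in weights.values() if w <= obs) / total


def brute_force_hmm_posteriors(
    haplotypes: np.ndarray,
    logliks: list[np.ndarray],
    pairs_per_locus: list[list[tuple[int, int]]],
    positions: list[int],
    rho: float,
) -> list[np.ndarray]:
    """Genotype posteriors by exhaustive enumeration over state paths."""
    N, L = haplotypes.shape[0], len(logliks)
    states = [(i, j) for i in range(N) for j in range(N)]

    def trans(d, h_from, h_to):
        q = 1.0 - math.exp(-rho * d)
        return (1.0 - q) + q / N if h_from == h_to else q / N

    def emit(l, st):
        a = sorted((haplotypes[st[0], l], haplotypes[st[1], l]))
        g = pairs_per_locus[l].index((a[0], a[1]))
        return math.exp(logliks[l][g])

    import itertools

    path_probs: dict[tuple, float] = {}
    for path in itertools.product(states, repeat=L):
        p = emit(0, path[0]) / (N * N)
        for l in range(1, L):
            d = max(positions[l] - positions[l - 1], 1)
            p *= trans(d, path[l - 1][0], path[l][0])
            p *= trans(d, path[l - 1][1], path[l][1])
            p *= emit(l, path[l])
        path_probs[path] = p
    total = sum(path_probs.values())
    out = []
    for l in range(L):
        post = np.zeros(len(pairs_per_locus[l])
                        )
        for path, p in path_probs.items():
            st = path[l]
            a = sorted((haplotypes[st[0], l], haplotypes[st[1], l]))
            post[pairs_per_locus[l].index((a[0], a[1]))] += p
        out.append(post / total)
    return out


def naive_containment(a: set[str], b: set[str]) -> float:
    return len(a & b) / len(a)
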