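"""Alignment-free sample QC and cohort partitioning with sketches.

Builds FracMinHash sketches for samples from two divergent
populations (half of them 'male': their reads include a chrY
segment), infers sex from chrY containment, subtracts chrY, and
partitions the cohort by average-linkage clustering of containment
distances.
"""

import numpy as np

from popccdg import build_sketch, partition_cohort, qc_sample

rng = np.random.default_rng(5)


def dna(n):
    return "".join(rng.choice(list("ACGT"), size=n))


L = 40_000
autosome = dna(L)
chry = dna(15_000)

# two populations diverged ~2%
pops = []
for _ in range(2):
    g = list(autosome)
    for p in rng.choice(L, size=L // 50, replace=False):
        g[p] = "ACGT"[("ACGT".index(g[p]) + 1) % 4]
    pops.append("".join(g))

samples, labels = [], []
for pi, founder in enumerate(pops):
    for i in range(6):
        g = list(founder)
        for p in rng.choice(L, size=L // 500, replace=False):
            g[p] = "ACGT"[("ACGT".index(g[p]) + 1) % 4]
        male = i % 2 == 0
        seqs = ["".join(g)] + ([chry] if male else [])
        samples.append(
            build_sketch(seqs, k=31, scale=10, with_abundance=True,
                         name=f"pop{pi}_s{i}{'m' if male else 'f'}")
        )
        labels.append(pi)

ref_sketch = build_sketch([autosome, chry], k=31, scale=10)
y_sketch = build_sketch([chry], k=31, scale=10)

for s in samples[:4]:
    rep = qc_sample(s, ref_sketch, y_sketch)
    print(
        f"{s.name}: breadth {rep.coverage_breadth:.2f}, "
        f"chrY containment {rep.chry_containment:.2f} -> {rep.sex_call}"
    )

parts = partition_cohort(samples, y_sketch, min_size=3, max_size=8)
for i, part in enumerate(parts):
    print(f"partition {i}: {[samples[j].name for j in part]}")
# With chrY subtracted, partitions follow population ancestry rather
# than sex; without it, males and females would cluster separately.
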