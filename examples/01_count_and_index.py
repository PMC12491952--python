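"""Build a small population count index from simulated reads.

Simulates a 60 kb diploid cohort of 4 samples at 20x, counts canonical
31-mers per sample (minimum count 3 drops likely sequencing errors),
smooths counts along unitigs, and merges everything into one index.
"""

import numpy as np

from popccdg import build_index, count_kmers, estimate_depth, smooth_by_unitig
from popccdg.simulate import (
    SimConfig,
    simulate_cohort,
    simulate_founders,
    simulate_reads,
    simulate_reference,
)

cfg = SimConfig(
    ref_length=60_000, n_founders=4, n_snp=60, n_small_indel=10,
    n_sv_indel=5, n_samples=4, depth=20.0, seed=7,
)
ref = simulate_reference(cfg)
truth = simulate_cohort(simulate_founders(ref, cfg), cfg)

tables = []
for s, sid in enumerate(truth.sample_ids):
    reads = simulate_reads(
        (truth.haplotype_sequence(2 * s), truth.haplotype_sequence(2 * s + 1)),
        cfg,
        seed=100 + s,
    )
    raw = count_kmers(reads, k=31, min_count=3, sample_id=sid)
    smooth = smooth_by_unitig(raw)
    print(
        f"{sid}: {len(raw)} k-mers, "
        f"depth estimate {estimate_depth(smooth):.1f} "
        f"(expected ~{cfg.depth * (cfg.read_length - 31 + 1) / cfg.read_length:.1f} "
        "in k-mer units)"
    )
    tables.append(smooth)

index = build_index(tables)
print(
    f"\nindex: {index.kmers.size} k-mers x {len(index.samples)} samples; "
    f"mean count {index.counts.mean():.1f}"
)
# Depth estimates are per-sample lambdas for the Poisson emission model;
# the k-mer count matrix is all the genotyper ever needs from the reads.
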