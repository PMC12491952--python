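"""Genotype a variant panel with the k-mer-only and HMM workflows.

Simulates a cohort with known truth, indexes it, extracts allele-unique
k-mers for the founder variant panel, and compares the emission-only
(k-mer) genotyper with the Li-Stephens HMM genotyper against truth.
"""

import os
import tempfile

import numpy as np

from popccdg import (
    build_index,
    count_kmers,
    extract_unique_kmers,
    genotype_partition,
    load_panel,
    smooth_by_unitig,
)
from popccdg.simulate import (
    SimConfig,
    simulate_cohort,
    simulate_founders,
    simulate_reads,
    simulate_reference,
    write_fasta,
    write_founder_vcf,
)

cfg = SimConfig(
    ref_length=80_000, n_founders=6, n_snp=80, n_small_indel=15,
    n_sv_indel=6, n_samples=8, depth=20.0, seed=21,
)
ref = simulate_reference(cfg)
founders = simulate_founders(ref, cfg)
truth = simulate_cohort(founders, cfg)

tables = []
for s, sid in enumerate(truth.sample_ids):
    reads = simulate_reads(
        (truth.haplotype_sequence(2 * s), truth.haplotype_sequence(2 * s + 1)),
        cfg,
        seed=300 + s,
    )
    tables.append(smooth_by_unitig(count_kmers(reads, sample_id=sid)))
index = build_index(tables)

with tempfile.TemporaryDirectory() as d:
    write_fasta(os.path.join(d, "ref.fa"), truth.chrom, ref)
    write_founder_vcf(founders, os.path.join(d, "founders.vcf"))
    panel = load_panel(os.path.join(d, "founders.vcf"), os.path.join(d, "ref.fa"))
    panel = extract_unique_kmers(panel, os.path.join(d, "ref.fa"))

print(
    f"panel: {panel.n_loci} loci, "
    f"{int(panel.uninformative_mask().sum())} with no unique k-mer"
)

truth_gts = np.sort(truth.genotypes, axis=2)
for mode in ("kmer", "hmm"):
    cohort = genotype_partition(panel, index, mode=mode)
    called = np.sort(cohort.genotypes, axis=2)
    conc = (called == truth_gts).all(axis=2).mean()
    print(f"{mode:>4} workflow: genotype concordance {conc:.3f}")
# The HMM workflow uses the phased panel to impute loci the k-mers
# cannot measure, so its concordance should be at least as high.
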