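# popccdg

Population genotyping of small and structural variants from a reusable
k-mer count index.

Genotyping a new variant list across a large short-read cohort normally
means re-processing every sample's raw reads — the "N+1 problem": one
additional variant forces a full pass over terabytes of FASTQ.
`popccdg` decouples the two steps.  The expensive work happens once: each
sample's reads are reduced to canonical k-mer counts (error-filtered at
a minimum count of 3, smoothed along unitigs of the de Bruijn graph),
samples are QC'd and partitioned by FracMinHash sketch similarity, and
each partition becomes a persistent k-mer → per-sample-count index — a
desk-scale counting colored de Bruijn graph.  Any phased or unphased
VCF can then be genotyped against the index in seconds to minutes,
without touching a read again.

It is written for methods developers and population-genomics analysts
who want an inspectable, fully seeded implementation of this family of
methods that runs on simulated or small real data on a laptop.

## The model

For each variant locus, alleles are represented by k-mers that occur
exactly once across the reference genome plus all alternative allele
sequences.  For a sample with k-mer depth λ and error rate ε, a k-mer
of an allele with copy number c ∈ {0, 1, 2} in the genotype has
expected count

    μ(c) = c·λ/2 + ε·λ

and observed counts are scored under a censored Poisson likelihood
(the index drops raw counts below its minimum-count filter, so an
observed zero means "below threshold", not "absent"); each allele
contributes one effective observation.  Three workflows build on these
emissions:

- **k-mer-only** — per-locus posterior over copy-number assignments
  under a uniform prior; works on unphased input.
- **HMM** — a Li–Stephens haplotype-copying model over ordered pairs
  of panel haplotypes (switch probability 1 − exp(−ρd) per haplotype
  between loci d bp apart), genotyped by forward–backward; phased
  panels only.  Loci without unique k-mers are imputed through phase.
- **2-pass** — the k-mer-only cohort output is filtered, imputed and
  phased into a reference panel, which the HMM workflow then uses to
  re-genotype everyone; this phases and rescues unphased input.

The population is the quality filter: per locus, the median of
genotype confidences (top minus second posterior) across all samples
sets a variable threshold; calls strictly below it are discarded and
statistically re-imputed from a Hardy–Weinberg prior over the retained
calls.  Panel statistics (AF/AC/AN, exact Hardy–Weinberg test with a
p > 10⁻⁶ screen, D′/r² within 1-Mb windows) and a strict
zygosity-penalizing benchmark protocol (1/1 called against an 0/1
truth is a false positive, 0/1 against 1/1 a false negative) complete
the toolkit.

## A worked example

`examples/02_genotype_workflows.py` simulates an 80-kb cohort of 8
samples from 6 founder haplotypes (80 SNPs, 15 small indels, 6
structural indels) at 20×, indexes the reads, and genotypes the
founder panel both ways:

```
$ python examples/02_genotype_workflows.py
panel: 101 loci, 0 with no unique k-mer
kmer workflow: genotype concordance 0.980
 hmm workflow: genotype concordance 1.000
```

Concordance is the fraction of sample×locus genotypes exactly matching
the simulated truth.  The HMM matches or beats the emission-only
workflow because phase lets confident neighbors vote on weak loci; the
gap widens sharply at low coverage.  The other example scripts cover
indexing and depth estimation (`01`), the 2-pass workflow plus
AF/HWE/LD statistics (`03`), and sketch QC / sex inference / cohort
partitioning (`04`).

The same machinery is available from a shell:

```
popccdg simulate --seed 9 --out sim/
popccdg index build --reads sim/sample000.fastq.gz --sample-id s0 \
    --k 31 --min-count 3 --out part1.idx
popccdg genotype --workflow two_pass --index part1.idx \
    --panel sim/truth.vcf --reference sim/ref.fa --out run/ --seed 9
popccdg bench --test run/genotypes.vcf --truth sim/truth.vcf
```

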