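# Methods

`popccdg` genotypes small and structural variants in a cohort of
short-read samples from a reusable k-mer count index, without
alignment and without revisiting raw reads.  This note documents the
models, the parameters that matter, the numerical choices, and what
the synthetic benchmark does and does not demonstrate.

## The count index

Each sample's reads are decomposed into canonical k-mers (lexicographic
minimum of a k-mer and its reverse complement; windows containing a
non-ACGT symbol are skipped, never substituted).  Counts below
`min_count` (default 3) are discarded: at realistic depths, singleton
and doubleton k-mers are overwhelmingly sequencing errors.  Counts are
then smoothed along unitigs — maximal non-branching paths of the
de Bruijn graph induced by the retained k-mers, in the bidirected
convention (a node merges with a neighbor only through an edge that is
unique on both touched sides) — with every member k-mer receiving the
path's rounded (ties-to-even) mean count.  Smoothing collapses
per-k-mer noise to per-unitig values at a nominal accuracy cost and is
the only count preprocessing enabled by default; logarithmic count
compression and graph cleaning are deliberately off, as both degrade
genotyping more than they save space.

Per-sample tables are merged into a partition index: the union of key
sets with one count column per sample, zeros for absent k-mers, and
counts capped at `ceil(3 * depth)` per sample to bound repeat-driven
blowup.  The on-disk container is a one-line JSON header (magic,
format version, k, per-sample depth/sex/partition) followed by sorted
`k-mer TAB counts` records; writing the same index twice is
byte-identical.

**Depth is in k-mer units.**  `estimate_depth` returns the modal
smoothed count restricted to `[min_count, 4 * median]`, falling back
to the median when that histogram is flat.  A read of length R covers
R − k + 1 full k-mer windows, so a genome sequenced at base depth D
yields an expected two-copy k-mer count of about D·(R−k+1)/R (21 at
30x with 100 bp reads and k = 31).  That k-mer-unit value is the
lambda used everywhere downstream; no conversion back to base depth is
ever needed.

k defaults to 31 for genotyping (packed 2-bit/uint64 fast path; odd k
only, so no reverse-complement palindromes).  Counting supports k up
to 63 through a byte-string fallback; unique-k-mer extraction and
genotyping require k ≤ 31.

## Allele-unique k-mers

A variant panel (sorted VCF + reference) becomes a list of merged,
non-overlapping loci.  Overlapping phased records merge into one
multi-allelic locus whose alternative alleles are the distinct local
haplotype strings observed across panel haplotypes; overlapping
unphased records are rejected (there is no defensible merge rule
without phase).  Indels below 50 bp of length change are small, at or
above 50 bp structural; multi-base substitutions and records with both
inserted and deleted content are complex.

Every allele receives a flanked sequence (`flank` defaults to 2(k−1),
giving interior as well as junction k-mers) and the k-mers that
identify it: a census counts each canonical k-mer's occurrences across
the full reference plus all alternative allele sequences (the
reference allele's own occurrence is already part of the reference —
counting it again would leave every reference allele k-mer-free), and
a k-mer is kept iff its census count is exactly 1, its window lies
within `flank` of the allele's edit, and no other allele claims it.
At most `cap` (default 300) k-mers are kept per allele, closest to the
edit first.  Alleles inside duplicated sequence can end with zero
k-mers; loci where every allele has zero are uninformative and can
only be imputed.

## Emission model

For a sample with k-mer depth lambda and error rate epsilon (default
0.01), a k-mer of an allele present with copy number c in {0, 1, 2}
has expected count

    mu(c) = c * lambda / 2 + epsilon * lambda

and each observed count contributes an independent Poisson log-term,
floored at −50 so a single contaminating k-mer cannot veto a genotype.
Counts are capped at `ceil(3 * lambda)` before evaluation.

The index is min-count filtered, and the likelihood accounts for that
censoring: an observed zero means "raw count below min_count" and
contributes log P(N < min_count | mu), not log P(N = 0 | mu).  This
matters enormously at low depth — at 5x base depth the two-copy k-mer
rate is ~3.5 and about three quarters of heterozygous k-mers fall
under a threshold of 3, so an uncensored model would read them as
confident absence and mis-call most heterozygotes; under the censored
model those zeros are only mildly informative, the confidence of such
calls drops, the median filter removes them, and the HMM/refiner
imputation recovers them from phase — which is exactly the regime
where phasing information is supposed to help.

The genotype log-likelihood sums over all alleles' k-mers; a locus
with no k-mers anywhere returns 0 for every genotype.  Poisson was
chosen as the simplest adequate family for smoothed counts at desk
scale; the additive `epsilon * lambda` mass absorbs sequencing errors
and stray repeat copies.

The k-mer-only genotyper applies a uniform prior over the copy-number
assignments summing to 2 and reports the posterior argmax, with
confidence defined as the gap between the highest and second-highest
posterior.  Uninformative loci yield a missing call with confidence 0.

## Li-Stephens HMM

With a phased panel of N haplotypes, hidden states are the N² ordered
haplotype pairs.  Between adjacent loci at distance d bp each copied
haplotype switches with probability q = 1 − exp(−rho·d), redistributed
uniformly (stay (1−q) + q/N, switch q/N each); the pair transition is
the product, applied in O(N²) via its rank-1 structure rather than the
N⁴ dense kernel.  Emissions are the genotype likelihoods implied by
the state's allele pair; forward–backward runs in scaled linear space
with per-locus normalization, and state posteriors are pooled over the
unordered allele pair to give genotype posteriors.  Uninformative loci
receive constant emissions and are thereby imputed from neighbors;
their calls are flagged.  rho defaults to 1e−6/bp, which makes
recombination visible but not saturating at the multi-kb locus
spacings of the simulated panels; it is exposed as `--rho` and was
fixed before any end-to-end evaluation.  Genotypes are reported
unphased here; final phase comes from the population refiner.

## Population refinement

Per locus, the median of the genotype confidences across all samples
is a variable quality threshold: calls strictly below the median are
discarded (ties retained, so at least half of every locus survives).
Discarded calls are re-imputed from the emission likelihood combined
with a Hardy–Weinberg prior built from the allele frequencies of the
retained calls; loci with no retained call fall back to a uniform
prior and carry an extra low-confidence flag.  Filtering happens after
partitions are aggregated, which is equivalent to per-partition
spilling followed by a merge (the map-reduce property is tested).

Phasing is an internal, seeded refiner in two stages.  A
haplotype-cluster EM (K = 8 latent clusters with per-locus allele
frequencies, pair-HMM posteriors, 15 EM rounds) produces the initial
phase; a cluster-pair Viterbi then assigns each heterozygous site's
alt allele to the chain whose cluster favors it.  Iterative refinement
(default 3 sweeps) re-phases each sample in fixed order by the
most-probable ordered-pair Viterbi path against the current haplotypes
of all other samples, genotype held fixed, with soft emissions
(mismatch weight 0.01 per allele).  Two numerical facts drove this
design: the ordered-pair posterior is exactly symmetric under swapping
the two copied chains, so per-locus marginals carry no phase
information and only a single decoded path does; and pure coordinate
ascent from random initial phases reliably converges to
self-consistent wrong optima (~20% switch error on founder-structured
cohorts), which the cluster-EM warm start avoids (~2–4%).  An
external-command hook (`{in_vcf}`/`{out_vcf}` template, VCF round-trip
validated) lets a full statistical refiner replace the internal one.

The 2-pass workflow chains everything: emission-only genotyping of the
unphased input builds a filtered, imputed, phased cohort panel;
its haplotypes — greedily subsampled to 32 by maximum minimum Hamming
distance, to keep the N² state space tractable — become the reference
panel for an HMM re-genotyping pass, followed by a second filter /
impute / phase round.  A pre-phased input skips pass 1.

## Panel statistics and benchmarking

AF/AC/AN count non-missing alleles; AF is null when all calls are
missing.  Hardy–Weinberg uses the exact conditional test (sum of
probabilities of heterozygote counts no more probable than observed,
given the allele counts), with a chi-square alternative for large
cohorts; loci with p ≤ 1e−6 are flagged.  LD is computed from phased
haplotypes within a window (default 1 Mb): D = p_AB − p_A p_B, D′
normalizes by the sign-appropriate bound, r² = D²/(p_A p_a p_B p_b);
multi-allelic loci collapse to major-allele-vs-rest and monomorphic
pairs are skipped, with r² > 0.8 the default reporting threshold.

Benchmarking assumes test and truth VCFs over the same variant set and
compares genotypes strictly: an exact match on a variant-carrying
genotype is a TP; calling a higher alt dosage than the truth (1/1
vs 0/1, or any call at a 0/0 truth) is an FP; a lower dosage (0/1
vs 1/1, or a missing call at a variant truth) is an FN; equal-dosage
allele mismatches at multi-allelic sites count as FP.  Sites where
neither file carries the variant are not tallied — a concordant
homozygous-reference pair is not an event.  Precision = TP/(TP+FP),
recall = TP/(TP+FN), F1 their harmonic mean, each null (never 0) on an
empty denominator, stratified by variant class and by overlap with
repeat intervals (BED, half-open; a variant abutting an interval end
is outside).

## Sketch QC and partitioning

FracMinHash sketches keep every canonical k-mer whose 64-bit hash
(blake2b, 8-byte digest, version-pinned) falls below 2⁶⁴/scale;
defaults k = 51, scale = 10000.  Containment of the reference sketch
gives coverage breadth; mean abundance of reference-shared hashes
gives a depth estimate; chrY containment calls sex (male above 0.30,
female below 0.20, ambiguous — flagged, never guessed — between;
thresholds sit far from both observed cohort means, ~0.65 for males
and ~0.08 for females).  For partitioning, chrY hashes are subtracted
from every sketch first (otherwise sex dominates the clustering),
pairwise distance is 1 − max(containment(a,b), containment(b,a)) for
robustness to unequal sketch sizes, and the average-linkage dendrogram
is cut greedily top-down so each partition fits `max_size`, with
undersized leftovers merged into their nearest partition.  Production
partition sizes are bounded at 100–350 samples.

## Synthetic data

The simulator emulates a haplotype-resolved truth experiment at desk
scale: an i.i.d. reference at configurable GC (default 0.41,
human-like); SNPs, indels, structural indels (size range configurable,
default 50–500 bp) and complex substitutions placed on founder
haplotypes at non-overlapping positions with a minimum 70 bp gap; each
variant's founder carrier count drawn uniformly so marginal allele
frequencies spread over (0, 1); cohort samples as diploid founder
mosaics with Poisson crossovers (default 1e−5/bp, ~3 per 300 kb
haplotype); and uniform 100 bp reads from both haplotypes with
substitution-only errors at 0.002 (substitution-only keeps k-mer error
behavior analyzable).  Everything is deterministic per seed, and truth
genotypes derive exactly from the mosaics.

What this does not emulate: indel sequencing errors, coverage bias,
PCR duplicates, mappability structure, real repeat landscapes (the
reference is random, so unique k-mers are easier to find than in a
human genome), population demography beyond a founder pool, and
contamination.  Passing the synthetic benchmark therefore demonstrates
the correctness of the machinery and the qualitative behavior of the
workflows (phasing information compensating for thin coverage), not
F-scores transferable to real genomes.

## Problem sizes and defaults

The end-to-end benchmark experiment uses the simulator defaults: a
300 kb reference, 8 founder haplotypes, 400 SNPs + 60 small indels +
25 structural indels (50–500 bp), 25 samples, 100 bp reads at 0.2%
error, 30x depth with a 5x companion run for the coverage-degradation
comparison.  On one CPU the full 30x experiment (read simulation,
counting, smoothing, indexing, three workflows, refinement and
scoring) runs in a few minutes; the 5x run is proportionally cheaper.

## Known limitations

Autosomal diploid only; no copy-number genotyping; symbolic and
breakend alleles rejected; panels beyond ~200 haplotypes make the N²
HMM state space impractical; the internal refiner is a deliberate
approximation of a full statistical phaser — for production cohorts,
plug one in through the external-command hook.
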