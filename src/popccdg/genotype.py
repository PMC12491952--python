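"""Genotype likelihoods from indexed k-mer counts.

Emissions: allele-unique k-mer counts are scored against a censored
Poisson model.  With sample depth lambda (the expected count of a
k-mer carried by both haplotypes) and error rate epsilon, a k-mer of
an allele with copy number c in the genotype has expected count

    mu(c) = c * lambda / 2 + epsilon * lambda

so absent alleles still allow a small error mass; an observed zero is
censored (the index drops raw counts below its min_count).  Per-k-mer
log-terms are floored to keep a single contaminating k-mer from
vetoing a genotype, and each allele contributes the MEAN of its
per-k-mer terms — its k-mers are covered by the same reads and share
smoothed unitigs, so they act as one observation, not as independent
replicates.

Unphased loci are genotyped from emissions alone under a uniform prior
(the k-mer-only workflow).  Phased panels use a Li-Stephens
haplotype-copying HMM: hidden states are ordered pairs of panel
haplotypes, each copied haplotype switches between loci at distance d
with probability q = 1 - exp(-rho * d) (redistributed uniformly over
haplotypes), and forward-backward posteriors are summed over states
mapping to the same unordered allele pair.  Loci without any unique
k-mer receive constant emissions and are thereby imputed from their
neighbors through the phasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations_with_replacement

import numpy as np
from scipy.special import gammaln

from .errors import ValidationError
from .kmer_index import PopulationIndex
from .panel import VariantPanel

DEFAULT_ERROR_RATE = 0.01
DEFAULT_FLOOR_LOGPROB = -50.0
DEFAULT_RHO = 1e-6  # per-bp haplotype switch intensity

FLAG_FILTERED = 1
FLAG_IMPUTED = 2
FLAG_UNINFORMATIVE = 4


@dataclass
class EmissionParams:
    depth: float  # lambda: expected count of a two-copy k-mer
    error_rate: float = DEFAULT_ERROR_RATE
    count_cap: int | None = None  # defaults to ceil(3 * depth)
    floor_logprob: float = DEFAULT_FLOOR_LOGPROB
    min_count: int = 3  # index count filter; zeros are censored below it

    def __post_init__(self):
        if self.depth <= 0:
            raise ValidationError(f"depth must be > 0, got {self.depth}")
        if not 0 < self.error_rate < 1:
            raise ValidationError(
                f"error_rate must be in (0, 1), got {self.error_rate}"
            )
        if self.count_cap is None:
            self.count_cap = int(np.ceil(3 * self.depth))


@dataclass
class HMMParams:
    rho: float = DEFAULT_RHO

    def __post_init__(self):
        if self.rho < 0:
            raise ValidationError(f"rho must be >= 0, got {self.rho}")


@dataclass
class GenotypeCall:
    genotype: tuple[int, int] | None  # unordered allele pair, None = missing
    posteriors: np.ndarray  # over candidate genotypes, sums to 1
    confidence: float  # p_top - p_second
    flags: int = 0

    @property
    def filtered(self) -> bool:
        return bool(self.flags & FLAG_FILTERED)

    @property
    def imputed(self) -> bool:
        return bool(self.flags & FLAG_IMPUTED)

    @property
    def uninformative(self) -> bool:
        return bool(self.flags & FLAG_UNINFORMATIVE)


def genotype_pairs(n_alleles: int) -> list[tuple[int, int]]:
    """Candidate unordered genotypes, in a fixed deterministic order."""
    return list(combinations_with_replacement(range(n_alleles), 2))


def _copy_numbers(pair: tuple[int, int], n_alleles: int) -> np.ndarray:
    c = np.zeros(n_alleles, dtype=np.int64)
    c[pair[0]] += 1
    c[pair[1]] += 1
    return c


def poisson_logpmf(n, mu):
    n = np.asarray(n, dtype=np.float64)
    mu = np.asarray(mu, dtype=np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(
            mu > 0,
            n * np.log(np.where(mu > 0, mu, 1.0)) - mu - gammaln(n + 1),
            np.where(n == 0, 0.0, -np.inf),
        )
    return out


def censored_poisson_loglik(counts, mu, min_count: int):
    """Per-k-mer log-likelihood against a min-count-filtered index.

    Indexing drops raw counts below ``min_count``, so an observed zero
    means "raw count < min_count", with probability P(N < min_count);
    observed counts at or above the threshold keep the plain Poisson
    mass.  Without censoring, low-depth heterozygous k-mers (most of
    which fall under the threshold) would read as confident absence.
    """
    counts = np.asarray(counts, dtype=np.float64)
    mu = np.asarray(mu, dtype=np.float64)
    base = poisson_logpmf(counts, mu)
    if min_count <= 1:
        return base
    below = np.stack(
        [poisson_logpmf(np.full_like(mu, j), mu) for j in range(min_count)]
    )
    m = below.max(axis=0)
    zero_ll = m + np.log(np.exp(below - m).sum(axis=0))
    return np.where(counts == 0, zero_ll, base)


def emission_loglik(
    observed: list[np.ndarray],
    copy_numbers,
    params: EmissionParams,
) -> float:
    """Log-likelihood of per-allele unique-k-mer counts for one genotype.

    ``observed[a]`` holds the counts of allele a's unique k-mers in the
    sample; ``copy_numbers[a]`` in {0, 1, 2} must sum to 2.  Each
    allele contributes the mean per-k-mer log-term (its k-mers share
    reads and unitigs, so they are one effective observation, not
    independent ones).  Returns 0 when no allele has any k-mer
    (uninformative locus).
    """
    copy_numbers = np.asarray(copy_numbers)
    if copy_numbers.sum() != 2:
        raise ValidationError(
            f"copy numbers must sum to 2, got {copy_numbers.tolist()}"
        )
    if len(observed) != copy_numbers.size:
        raise ValidationError("one count array per allele required")
    lam, eps = params.depth, params.error_rate
    total = 0.0
    for counts, c in zip(observed, copy_numbers):
        counts = np.minimum(np.asarray(counts, dtype=np.float64), params.count_cap)
        if counts.size == 0:
            continue
        mu = np.full(counts.shape, c * lam / 2.0 + eps * lam)
        terms = np.maximum(
            censored_poisson_loglik(counts, mu, params.min_count),
            params.floor_logprob,
        )
        # an allele's k-mers are covered by the same reads (and smoothed
        # along shared unitigs), so they are far from independent: score
        # each allele by its mean per-k-mer term, one effective
        # observation per allele, instead of multiplying pseudo-
        # independent terms into arbitrarily confident evidence
        total += float(terms.mean())
    return total


# ---------------------------------------------------------------------------
# cohort-vectorized emission engine


class _EmissionEngine:
    """Per-locus genotype log-likelihoods for every sample of an index."""

    def __init__(
        self,
        panel: VariantPanel,
        index: PopulationIndex,
        error_rate: float = DEFAULT_ERROR_RATE,
        floor_logprob: float = DEFAULT_FLOOR_LOGPROB,
    ):
        if panel.allele_kmers is None:
            raise ValidationError(
                "panel has no allele k-mers; run extract_unique_kmers first"
            )
        self.panel = panel
        self.index = index
        self.error_rate = error_rate
        self.floor = floor_logprob
        self.min_count = getattr(index, "min_count", 3)
        self.lams = index.depths()
        if np.any(self.lams <= 0):
            raise ValidationError("all samples need a positive depth estimate")
        self.caps = np.ceil(3 * self.lams)
        # observed counts per locus per allele: (n_kmers, n_samples)
        self.obs = [
            [index.lookup(arr) for arr in per_locus]
            for per_locus in panel.allele_kmers
        ]
        self.pairs = [genotype_pairs(l.n_alleles) for l in panel.loci]
        self.uninformative = panel.uninformative_mask()
        self.kmer_totals = np.stack(
            [
                sum(o.sum(axis=0) for o in per_locus)
                for per_locus in self.obs
            ]
        )  # (n_loci, n_samples) summed allele k-mer counts, for KC output

    def locus_logliks(self, l: int) -> np.ndarray:
        """(n_genotypes, n_samples) emission log-likelihoods at locus l."""
        per_allele = self.obs[l]
        n_samples = self.lams.size
        # summed per-allele loglik for each copy number 0/1/2
        S = np.zeros((len(per_allele), 3, n_samples))
        for a, counts in enumerate(per_allele):
            if counts.shape[0] == 0:
                continue
            capped = np.minimum(counts, self.caps[None, :])
            for c in (0, 1, 2):
                mu = c * self.lams / 2.0 + self.error_rate * self.lams
                terms = np.maximum(
                    censored_poisson_loglik(
                        capped,
                        np.broadcast_to(mu[None, :], capped.shape),
                        self.min_count,
                    ),
                    self.floor,
                )
                S[a, c] = terms.mean(axis=0)  # one observation per allele
        out = np.zeros((len(self.pairs[l]), n_samples))
        for g, pair in enumerate(self.pairs[l]):
            cns = _copy_numbers(pair, len(per_allele))
            out[g] = sum(S[a, c] for a, c in enumerate(cns))
        return out

    def all_logliks(self) -> list[np.ndarray]:
        return [self.locus_logliks(l) for l in range(self.panel.n_loci)]


@dataclass
class CohortGenotypes:
    """Genotype calls for every locus x sample of one or more partitions."""

    panel: VariantPanel
    sample_ids: list[str]
    genotypes: np.ndarray  # (n_loci, n_samples, 2) int8; -1 = missing
    confidence: np.ndarray  # (n_loci, n_samples)
    flags: np.ndarray  # (n_loci, n_samples) uint8 bitmask
    gt_logliks: list[np.ndarray]  # per locus (n_genotypes, n_samples)
    depths: np.ndarray  # per sample
    partition_ids: np.ndarray  # per sample
    kmer_totals: np.ndarray | None = None  # (n_loci, n_samples)
    haplotypes: np.ndarray | None = None  # (2*n_samples, n_loci) once phased

    @property
    def n_loci(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[1]

    def missing_mask(self) -> np.ndarray:
        return self.genotypes[:, :, 0] < 0

    def call(self, l: int, s: int) -> GenotypeCall:
        gt = self.genotypes[l, s]
        pairs = genotype_pairs(self.panel.loci[l].n_alleles)
        ll = self.gt_logliks[l][:, s]
        w = np.exp(ll - ll.max())
        return GenotypeCall(
            genotype=None if gt[0] < 0 else (int(gt[0]), int(gt[1])),
            posteriors=w / w.sum(),
            confidence=float(self.confidence[l, s]),
            flags=int(self.flags[l, s]),
        )


def _calls_from_posteriors(
    post: np.ndarray, pairs: list[tuple[int, int]]
) -> tuple[np.ndarray, np.ndarray]:
    """Argmax genotype and top-minus-second confidence per sample."""
    n_samples = post.shape[1]
    top_idx = post.argmax(axis=0)
    gts = np.array([pairs[i] for i in top_idx], dtype=np.int8)
    srt = np.sort(post, axis=0)
    conf = srt[-1] - (srt[-2] if post.shape[0] > 1 else np.zeros(n_samples))
    return gts, conf


def genotype_partition(
    panel: VariantPanel,
    index: PopulationIndex,
    mode: str = "kmer",
    hmm: HMMParams | None = None,
    error_rate: float = DEFAULT_ERROR_RATE,
    floor_logprob: float = DEFAULT_FLOOR_LOGPROB,
) -> CohortGenotypes:
    """Genotype every sample of one partition index.

    ``mode='kmer'`` uses emissions only (works for unphased panels);
    ``mode='hmm'`` runs the Li-Stephens forward-backward and requires a
    phased panel.  Samples are independent, so results do not depend on
    processing order.
    """
    if mode not in ("kmer", "hmm"):
        raise ValidationError(f"unknown mode {mode!r}")
    engine = _EmissionEngine(panel, index, error_rate, floor_logprob)
    logliks = engine.all_logliks()
    n_loci, n_samples = panel.n_loci, len(index.samples)
    genotypes = np.full((n_loci, n_samples, 2), -1, dtype=np.int8)
    confidence = np.zeros((n_loci, n_samples))
    flags = np.zeros((n_loci, n_samples), dtype=np.uint8)
    flags[engine.uninformative, :] |= FLAG_UNINFORMATIVE

    if mode == "kmer":
        for l in range(n_loci):
            if engine.uninformative[l]:
                continue  # missing call, confidence 0
            ll = logliks[l]
            w = np.exp(ll - ll.max(axis=0, keepdims=True))
            post = w / w.sum(axis=0, keepdims=True)
            genotypes[l], confidence[l] = _calls_from_posteriors(
                post, engine.pairs[l]
            )
    else:
        if not panel.phased:
            raise ValidationError("HMM mode requires a phased panel")
        if panel.n_haplotypes < 2:
            raise ValidationError("HMM mode needs at least 2 panel haplotypes")
        hmm = hmm or HMMParams()
        flags[engine.uninformative, :] |= FLAG_IMPUTED
        for s in range(n_samples):
            post_per_locus = _hmm_genotype_posteriors(
                panel, [ll[:, s] for ll in logliks], hmm
            )
            for l in range(n_loci):
                post = post_per_locus[l][:, None]
                gt, conf = _calls_from_posteriors(post, engine.pairs[l])
                genotypes[l, s] = gt[0]
                confidence[l, s] = conf[0]
    return CohortGenotypes(
        panel=panel,
        sample_ids=index.sample_ids,
        genotypes=genotypes,
        confidence=confidence,
        flags=flags,
        gt_logliks=logliks,
        depths=index.depths(),
        partition_ids=np.array([s.partition_id for s in index.samples]),
        kmer_totals=engine.kmer_totals,
    )


def genotype_kmer_only(
    panel: VariantPanel, index: PopulationIndex, sample_id: str
) -> list[GenotypeCall]:
    """Emission-only genotypes of one sample (uniform prior argmax)."""
    cohort = genotype_partition(panel, index, mode="kmer")
    s = index.sample_index(sample_id)
    return [cohort.call(l, s) for l in range(cohort.n_loci)]


def genotype_hmm(
    panel: VariantPanel,
    index: PopulationIndex,
    sample_id: str,
    hmm: HMMParams | None = None,
) -> list[GenotypeCall]:
    """Li-Stephens HMM genotypes of one sample against a phased panel."""
    if not panel.phased:
        raise ValidationError("HMM genotyping requires a phased panel")
    if panel.n_haplotypes < 2:
        raise ValidationError("HMM mode needs at least 2 panel haplotypes")
    hmm = hmm or HMMParams()
    engine = _EmissionEngine(panel, index)
    s = index.sample_index(sample_id)
    logliks = [engine.locus_logliks(l)[:, s] for l in range(panel.n_loci)]
    posts = _hmm_genotype_posteriors(panel, logliks, hmm)
    out = []
    for l, post in enumerate(posts):
        gt, conf = _calls_from_posteriors(post[:, None], engine.pairs[l])
        flags = 0
        if engine.uninformative[l]:
            flags |= FLAG_UNINFORMATIVE | FLAG_IMPUTED
        out.append(
            GenotypeCall(
                genotype=(int(gt[0, 0]), int(gt[0, 1])),
                posteriors=post,
                confidence=float(conf[0]),
                flags=flags,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Li-Stephens forward-backward over ordered haplotype pairs


def _interval_switch_probs(panel: VariantPanel, rho: float) -> np.ndarray:
    """Per-haplotype switch probability q for each adjacent locus pair."""
    loci = panel.loci
    q = np.empty(max(len(loci) - 1, 0))
    for i in range(len(loci) - 1):
        if loci[i + 1].chrom != loci[i].chrom:
            q[i] = 1.0  # independent chromosomes: full reset
        else:
            d = max(loci[i + 1].pos - loci[i].pos, 1)
            q[i] = 1.0 - np.exp(-rho * d)
    return q


def _pair_transition(M: np.ndarray, a: float, b: float) -> np.ndarray:
    """Apply the Kronecker transition (A x A), A = a*I + b*J, to M."""
    rowsum = M.sum(axis=1, keepdims=True)
    colsum = M.sum(axis=0, keepdims=True)
    total = rowsum.sum()
    return a * a * M + a * b * (rowsum + colsum) + b * b * total


def _hmm_genotype_posteriors(
    panel: VariantPanel,
    logliks: list[np.ndarray],
    hmm: HMMParams,
) -> list[np.ndarray]:
    """Per-locus genotype posteriors for one sample.

    ``logliks[l]`` are emission log-likelihoods over the candidate
    genotypes of locus l.  Scaled forward-backward over the N^2 ordered
    haplotype pairs, then state posteriors are pooled by unordered
    allele pair.
    """
    H = panel.haplotypes
    N, L = H.shape[0], panel.n_loci
    if L == 0:
        return []
    q = _interval_switch_probs(panel, hmm.rho)

    # per-locus state emission matrices and state->genotype maps
    emissions: list[np.ndarray] = []
    gids: list[np.ndarray] = []
    for l in range(L):
        pairs = genotype_pairs(panel.loci[l].n_alleles)
        pair_to_gid = {p: g for g, p in enumerate(pairs)}
        al = H[:, l].astype(np.int64)
        a1 = np.minimum(al[:, None], al[None, :])
        a2 = np.maximum(al[:, None], al[None, :])
        gid = np.empty((N, N), dtype=np.int64)
        for g, p in enumerate(pairs):
            gid[(a1 == p[0]) & (a2 == p[1])] = g
        ll = logliks[l]
        E = np.exp(ll - ll.max())[gid]
        emissions.append(E)
        gids.append(gid)

    fwd = np.empty((L, N, N))
    F = emissions[0] / (N * N)
    F /= F.sum()
    fwd[0] = F
    for l in range(1, L):
        a, b = 1.0 - q[l - 1], q[l - 1] / N
        F = _pair_transition(fwd[l - 1], a, b) * emissions[l]
        F /= F.sum()
        fwd[l] = F

    post = [None] * L
    B = np.ones((N, N))
    for l in range(L - 1, -1, -1):
        P = fwd[l] * B
        P /= P.sum()
        G = len(genotype_pairs(panel.loci[l].n_alleles))
        post[l] = np.bincount(gids[l].ravel(), weights=P.ravel(), minlength=G)
        if l > 0:
            a, b = 1.0 - q[l - 1], q[l - 1] / N
            B = _pair_transition(B * emissions[l], a, b)
            B /= B.sum()
    return post
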