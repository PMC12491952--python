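"""Population-level refinement of cohort genotypes.

The population is what single-sample genotypers lack: with calls for
the same locus across hundreds of samples, the per-locus median of the
genotype confidences becomes a variable quality threshold (high for
k-mer-rich variants, low for hard ones), calls falling strictly below
it are discarded, and the retained high-confidence calls form a
reference panel used to statistically impute the discarded ones and to
phase the cohort.  The 2-pass workflow applies this machinery twice:
emission-only genotyping builds a phased panel from scratch, and the
Li-Stephens HMM then re-genotypes every sample against that panel.

The imputation/phasing refiner here is a documented internal
approximation (Hardy-Weinberg-prior imputation plus iterative
posterior-decoding phasing); an external-command hook with a VCF
round-trip contract lets a full statistical refiner be swapped in.
"""

from __future__ import annotations

import copy as _copy
import shlex
import subprocess
import tempfile
from dataclasses import dataclass, field

import numpy as np

from .errors import ConsistencyError, RefinerError, ValidationError
from .genotype import (
    FLAG_FILTERED,
    FLAG_IMPUTED,
    FLAG_UNINFORMATIVE,
    CohortGenotypes,
    HMMParams,
    _pair_transition,
    genotype_pairs,
    genotype_partition,
    _interval_switch_probs,
)
from .panel import VariantPanel

FLAG_LOWCONF_IMPUTED = 8

DEFAULT_PHASE_ITERATIONS = 3
DEFAULT_PANEL_HAPLOTYPES = 32
_PHASE_MISMATCH_WEIGHT = 0.01  # soft emission per mismatched allele


@dataclass
class FilterReport:
    thresholds: np.ndarray  # per-locus median confidence
    retained: np.ndarray  # per-locus retained call count
    filtered: np.ndarray  # per-locus removed call count


@dataclass
class RefinerConfig:
    backend: str = "internal"  # or "external_command"
    iterations: int = DEFAULT_PHASE_ITERATIONS
    seed: int = 0
    command_template: str | None = None  # "{in_vcf}" / "{out_vcf}"
    rho: float = HMMParams().rho

    def __post_init__(self):
        if self.backend not in ("internal", "external_command"):
            raise ValidationError(f"unknown refiner backend {self.backend!r}")
        if self.backend == "external_command" and not self.command_template:
            raise ValidationError(
                "external_command backend requires a command_template"
            )


def _clone(cohort: CohortGenotypes) -> CohortGenotypes:
    return CohortGenotypes(
        panel=cohort.panel,
        sample_ids=list(cohort.sample_ids),
        genotypes=cohort.genotypes.copy(),
        confidence=cohort.confidence.copy(),
        flags=cohort.flags.copy(),
        gt_logliks=[x.copy() for x in cohort.gt_logliks],
        depths=cohort.depths.copy(),
        partition_ids=cohort.partition_ids.copy(),
        kmer_totals=(
            None if cohort.kmer_totals is None else cohort.kmer_totals.copy()
        ),
        haplotypes=(
            None if cohort.haplotypes is None else cohort.haplotypes.copy()
        ),
    )


def aggregate_partitions(parts: list[CohortGenotypes]) -> CohortGenotypes:
    """Column-concatenate per-partition cohorts (map-reduce merge)."""
    if not parts:
        raise ValidationError("no partitions to aggregate")
    first = parts[0]
    for p in parts[1:]:
        if p.panel is not first.panel and [
            (l.chrom, l.pos, l.ref_allele, tuple(l.alt_alleles))
            for l in p.panel.loci
        ] != [
            (l.chrom, l.pos, l.ref_allele, tuple(l.alt_alleles))
            for l in first.panel.loci
        ]:
            raise ConsistencyError("partitions genotyped against different panels")
    ids = [sid for p in parts for sid in p.sample_ids]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate sample ids across partitions")
    return CohortGenotypes(
        panel=first.panel,
        sample_ids=ids,
        genotypes=np.concatenate([p.genotypes for p in parts], axis=1),
        confidence=np.concatenate([p.confidence for p in parts], axis=1),
        flags=np.concatenate([p.flags for p in parts], axis=1),
        gt_logliks=[
            np.concatenate([p.gt_logliks[l] for p in parts], axis=1)
            for l in range(first.n_loci)
        ],
        depths=np.concatenate([p.depths for p in parts]),
        partition_ids=np.concatenate([p.partition_ids for p in parts]),
        kmer_totals=(
            None
            if any(p.kmer_totals is None for p in parts)
            else np.concatenate([p.kmer_totals for p in parts], axis=1)
        ),
    )


def median_confidence_filter(
    cohort: CohortGenotypes,
) -> tuple[CohortGenotypes, FilterReport]:
    """Discard calls whose confidence falls strictly below the
    per-locus median confidence across samples.

    Ties at the median are retained, so at least half the calls of
    every locus survive.  Filtered calls become missing and are flagged
    for imputation.
    """
    if cohort.n_loci == 0 or cohort.n_samples == 0:
        raise ValidationError("cannot filter an empty cohort")
    out = _clone(cohort)
    thresholds = np.median(cohort.confidence, axis=1)
    below = cohort.confidence < thresholds[:, None]
    out.genotypes[below] = -1
    out.flags[below] |= FLAG_FILTERED
    retained = (~below).sum(axis=1)
    return out, FilterReport(
        thresholds=thresholds,
        retained=retained,
        filtered=below.sum(axis=1),
    )


def _retained_allele_freqs(cohort: CohortGenotypes, l: int) -> np.ndarray | None:
    """Allele frequencies among non-missing calls at locus l."""
    n_alleles = cohort.panel.loci[l].n_alleles
    gts = cohort.genotypes[l]
    present = gts[:, 0] >= 0
    if not present.any():
        return None
    counts = np.bincount(gts[present].ravel(), minlength=n_alleles).astype(float)
    return counts / counts.sum()


def impute_missing(
    cohort: CohortGenotypes,
    panel: VariantPanel | None = None,
    config: RefinerConfig | None = None,
) -> CohortGenotypes:
    """Fill missing calls from emissions and a population prior.

    Internal backend: posterior over genotypes proportional to the
    stored emission likelihood times a Hardy-Weinberg prior built from
    the allele frequencies of the retained calls at the locus; the
    argmax is flagged imputed.  Loci with no retained call fall back to
    a uniform prior and are additionally flagged low-confidence.
    Retained calls are untouched.
    """
    config = config or RefinerConfig()
    if config.backend == "external_command":
        return _external_refine(cohort, config, phase=False)
    out = _clone(cohort)
    for l in range(cohort.n_loci):
        missing = np.flatnonzero(cohort.genotypes[l, :, 0] < 0)
        if missing.size == 0:
            continue
        pairs = genotype_pairs(cohort.panel.loci[l].n_alleles)
        freqs = _retained_allele_freqs(cohort, l)
        if freqs is None:
            prior = np.ones(len(pairs))
            extra_flag = FLAG_LOWCONF_IMPUTED
        else:
            prior = np.array(
                [
                    (2.0 if a != b else 1.0) * freqs[a] * freqs[b]
                    for a, b in pairs
                ]
            )
            prior = np.maximum(prior, 1e-12)
            extra_flag = 0
        ll = cohort.gt_logliks[l][:, missing]
        logpost = ll + np.log(prior)[:, None]
        w = np.exp(logpost - logpost.max(axis=0, keepdims=True))
        post = w / w.sum(axis=0, keepdims=True)
        top = post.argmax(axis=0)
        for j, s in enumerate(missing):
            out.genotypes[l, s] = pairs[top[j]]
            out.flags[l, s] |= FLAG_IMPUTED | extra_flag
    return out


# ---------------------------------------------------------------------------
# phasing


def _phase_emissions(
    hap_alleles: np.ndarray, gt: tuple[int, int]
) -> np.ndarray:
    """Soft emission matrix over ordered pairs of panel haplotypes.

    Weight = mismatch_weight ** (minimum allele mismatches against
    either orientation of the fixed genotype).  Panel entries of -1
    are unknown and match anything (used by the hom-anchored warm
    start, where heterozygous panel sites are masked).
    """
    a1 = hap_alleles[:, None]
    a2 = hap_alleles[None, :]
    g1, g2 = gt
    # unknown panel alleles count as half a mismatch: cheaper than a
    # contradiction, dearer than a confirmed match
    unk1 = (a1 < 0).astype(np.float64)
    unk2 = (a2 < 0).astype(np.float64)
    mm_fwd = ((a1 != g1) & (a1 >= 0)) + ((a2 != g2) & (a2 >= 0))
    mm_rev = ((a1 != g2) & (a1 >= 0)) + ((a2 != g1) & (a2 >= 0))
    cost = np.minimum(mm_fwd, mm_rev) + 0.5 * (unk1 + unk2)
    return _PHASE_MISMATCH_WEIGHT ** cost


def _rephase_sample(
    panel: VariantPanel,
    other_haps: np.ndarray,
    genotypes: np.ndarray,  # (n_loci, 2), no missing
    current: np.ndarray,  # (2, n_loci) current phased alleles
    rho: float,
) -> np.ndarray:
    """Re-phase one sample against the other samples' haplotypes.

    Viterbi over ordered pairs of panel haplotypes with the genotype
    held fixed (soft emissions allow panel mismatches).  The ordered-
    pair posterior is symmetric under swapping the two copied chains,
    so only a single most-probable PATH — not per-locus marginals —
    carries phase information; each heterozygous locus takes the
    orientation of the path's state, and loci the panel cannot explain
    keep the orientation of the nearest explained locus.
    """
    N, L = other_haps.shape[0], panel.n_loci
    q = _interval_switch_probs(panel, rho)
    log_w = np.log(_PHASE_MISMATCH_WEIGHT)
    log_em = [
        np.log(
            _phase_emissions(other_haps[:, l].astype(np.int64), tuple(genotypes[l]))
        )
        for l in range(L)
    ]
    delta = np.empty((L, N, N))
    delta[0] = log_em[0]
    for l in range(1, L):
        a = 1.0 - q[l - 1] + q[l - 1] / N  # per-haplotype stay
        b = q[l - 1] / N  # per-haplotype switch
        la, lb = np.log(a), np.log(b)
        M = delta[l - 1]
        rowmax = M.max(axis=1, keepdims=True)
        colmax = M.max(axis=0, keepdims=True)
        gmax = M.max()
        best = np.maximum(M + 2 * la, gmax + 2 * lb)
        best = np.maximum(best, rowmax + la + lb)
        best = np.maximum(best, colmax + la + lb)
        delta[l] = log_em[l] + best
        delta[l] -= delta[l].max()  # rescale; argmax structure unchanged

    # traceback of one optimal path (ties -> lowest flat index)
    path = np.empty((L, 2), dtype=np.int64)
    flat = int(delta[L - 1].argmax())
    path[L - 1] = divmod(flat, N)
    for l in range(L - 1, 0, -1):
        i, j = path[l]
        a = 1.0 - q[l - 1] + q[l - 1] / N
        b = q[l - 1] / N
        la, lb = np.log(a), np.log(b)
        M = delta[l - 1]
        score = M + lb + lb
        score[i, :] += la - lb
        score[:, j] += la - lb
        flat = int(score.argmax())
        path[l - 1] = divmod(flat, N)

    out = current.copy()
    carry = None  # orientation of the previous explained het locus
    for l in range(L):
        g1, g2 = genotypes[l]
        if g1 == g2:
            out[:, l] = (g1, g2)
            continue
        i, j = path[l]
        a1, a2 = int(other_haps[i, l]), int(other_haps[j, l])
        if {a1, a2} == {g1, g2} and a1 != a2:
            out[:, l] = (a1, a2)
            carry = (a1, a2) == (g1, g2)
        elif carry is not None:
            out[:, l] = (g1, g2) if carry else (g2, g1)
        # else: keep current orientation until the first explained het
    return out


def _cluster_em_phase(
    panel: VariantPanel,
    genotypes: np.ndarray,  # (n_loci, n_samples, 2), sorted, no missing
    rho: float,
    seed: int,
    n_clusters: int = 8,
    n_iter: int = 15,
) -> np.ndarray:
    """Initial phasing via a haplotype-cluster frequency model.

    Haplotypes are modelled as mosaics of K latent clusters with
    per-locus allele-1 frequencies theta[k, l]; EM alternates pair-HMM
    posteriors with frequency updates, and a final cluster-pair
    Viterbi per sample assigns the alt allele of each heterozygous
    site to the chain whose cluster favors it.  Multi-allelic sites
    collapse to alt-vs-ref for this step.  Returns (2n, L) haplotypes.
    """
    L, n, _ = genotypes.shape
    K = min(n_clusters, max(2, 2 * n))
    rng = np.random.default_rng(seed)
    dosage = (genotypes > 0).sum(axis=2)  # (L, n) in {0,1,2}
    af = np.clip(dosage.mean(axis=1) / 2.0, 0.05, 0.95)
    theta = np.clip(
        af[None, :] + rng.uniform(-0.3, 0.3, size=(K, L)), 0.02, 0.98
    )
    q = _interval_switch_probs(panel, rho)

    def emissions(theta, d):
        """(L, K, K) genotype likelihood per cluster pair for dosages d."""
        t1 = theta.T[:, :, None]  # (L, K, 1)
        t2 = theta.T[:, None, :]
        e = np.empty((L, K, K))
        hom_ref = (1 - t1) * (1 - t2)
        het = t1 * (1 - t2) + (1 - t1) * t2
        hom_alt = t1 * t2
        for l in range(L):
            e[l] = (hom_ref[l], het[l], hom_alt[l])[d[l]]
        return np.maximum(e, 1e-12)

    for _ in range(n_iter):
        w1 = np.zeros((K, L))
        usage = np.zeros((K, L))
        for s in range(n):
            E = emissions(theta, dosage[:, s])
            fwd = np.empty((L, K, K))
            F = E[0] / (K * K)
            F /= F.sum()
            fwd[0] = F
            for l in range(1, L):
                a, b = 1.0 - q[l - 1], q[l - 1] / K
                F = _pair_transition(fwd[l - 1], a, b) * E[l]
                F /= F.sum()
                fwd[l] = F
            B = np.ones((K, K))
            for l in range(L - 1, -1, -1):
                P = fwd[l] * B
                P /= P.sum()
                pk1 = P.sum(axis=1)
                pk2 = P.sum(axis=0)
                d = dosage[l, s]
                if d == 2:
                    w1[:, l] += pk1 + pk2
                elif d == 1:
                    t1 = theta[:, l][:, None]
                    t2 = theta[:, l][None, :]
                    r = t1 * (1 - t2) / np.maximum(
                        t1 * (1 - t2) + (1 - t1) * t2, 1e-12
                    )
                    w1[:, l] += (P * r).sum(axis=1) + (P * (1 - r)).sum(axis=0)
                usage[:, l] += pk1 + pk2
                if l > 0:
                    a, b = 1.0 - q[l - 1], q[l - 1] / K
                    B = _pair_transition(B * E[l], a, b)
                    B /= B.sum()
        theta = np.clip((w1 + 0.1) / (usage + 0.2), 0.01, 0.99)

    haps = np.zeros((2 * n, L), dtype=np.int8)
    for s in range(n):
        E = np.log(emissions(theta, dosage[:, s]))
        delta = np.empty((L, K, K))
        delta[0] = E[0]
        for l in range(1, L):
            a = 1.0 - q[l - 1] + q[l - 1] / K
            b = q[l - 1] / K
            la, lb = np.log(a), np.log(b)
            M = delta[l - 1]
            best = np.maximum(M + 2 * la, M.max() + 2 * lb)
            best = np.maximum(best, M.max(axis=1, keepdims=True) + la + lb)
            best = np.maximum(best, M.max(axis=0, keepdims=True) + la + lb)
            delta[l] = E[l] + best
            delta[l] -= delta[l].max()
        path = np.empty((L, 2), dtype=np.int64)
        path[L - 1] = divmod(int(delta[L - 1].argmax()), K)
        for l in range(L - 1, 0, -1):
            i, j = path[l]
            a = 1.0 - q[l - 1] + q[l - 1] / K
            b = q[l - 1] / K
            la, lb = np.log(a), np.log(b)
            score = delta[l - 1] + 2 * lb
            score[i, :] += la - lb
            score[:, j] += la - lb
            path[l - 1] = divmod(int(score.argmax()), K)
        g = genotypes[:, s, :]
        hap1 = g[:, 0].copy()
        hap2 = g[:, 1].copy()
        het = (dosage[:, s] == 1) & (g[:, 0] != g[:, 1])
        for l in np.flatnonzero(het):
            k1, k2 = path[l]
            lo, hi = sorted((g[l, 0], g[l, 1]))
            if theta[k1, l] >= theta[k2, l]:
                hap1[l], hap2[l] = hi, lo
            else:
                hap1[l], hap2[l] = lo, hi
        haps[2 * s] = hap1
        haps[2 * s + 1] = hap2
    return haps


def phase_cohort(
    cohort: CohortGenotypes,
    panel: VariantPanel | None = None,
    config: RefinerConfig | None = None,
) -> VariantPanel:
    """Phase a fully imputed cohort; returns the panel of cohort
    haplotypes (and stores them on the cohort).

    Internal backend: heterozygous sites get a seeded random initial
    orientation, then for a fixed number of rounds each sample is
    re-phased in fixed order against the current haplotypes of all
    other samples.  Homozygous sites are trivially phased.
    Deterministic given the seed.
    """
    panel = panel or cohort.panel
    config = config or RefinerConfig()
    if cohort.missing_mask().any():
        raise ValidationError("phase_cohort requires a fully imputed cohort")
    if config.backend == "external_command":
        refined = _external_refine(cohort, config, phase=True)
        cohort.haplotypes = refined.haplotypes
        return panel.with_haplotypes(
            refined.haplotypes,
            [f"{sid}_h{i}" for sid in cohort.sample_ids for i in (1, 2)],
        )
    rng = np.random.default_rng(config.seed)
    n, L = cohort.n_samples, cohort.n_loci
    haps = np.zeros((2 * n, L), dtype=np.int8)
    for s in range(n):
        gts = cohort.genotypes[:, s, :]
        flip = rng.integers(0, 2, size=L).astype(bool)
        first = np.where(flip, gts[:, 1], gts[:, 0])
        second = np.where(flip, gts[:, 0], gts[:, 1])
        haps[2 * s] = first
        haps[2 * s + 1] = second
    if n > 1:
        # warm start: haplotype-cluster EM gives a coherent initial
        # phase (coordinate ascent alone is prone to self-consistent
        # wrong optima when every sample starts random)
        haps = _cluster_em_phase(
            panel,
            np.sort(cohort.genotypes, axis=2).astype(np.int8),
            config.rho,
            config.seed,
        )
        for _ in range(config.iterations):
            for s in range(n):
                other = np.delete(haps, [2 * s, 2 * s + 1], axis=0)
                haps[2 * s : 2 * s + 2] = _rephase_sample(
                    panel,
                    other,
                    cohort.genotypes[:, s, :],
                    haps[2 * s : 2 * s + 2],
                    config.rho,
                )
    cohort.haplotypes = haps
    names = [f"{sid}_h{i}" for sid in cohort.sample_ids for i in (1, 2)]
    return panel.with_haplotypes(haps, names)


def subsample_haplotypes(
    haplotypes: np.ndarray, n: int = DEFAULT_PANEL_HAPLOTYPES
) -> np.ndarray:
    """Greedy max-diversity subsample of haplotype rows.

    Keeps the HMM state space tractable when a large phased cohort
    feeds back into pass 2.  Starts from row 0 and repeatedly adds the
    haplotype maximizing the minimum Hamming distance to the chosen
    set (ties broken by lowest index); deterministic.
    """
    H = np.asarray(haplotypes)
    if H.shape[0] <= n:
        return H.copy()
    chosen = [0]
    dist = (H != H[0]).sum(axis=1)
    for _ in range(n - 1):
        dist[chosen] = -1
        nxt = int(dist.argmax())
        chosen.append(nxt)
        dist = np.minimum(dist, (H != H[nxt]).sum(axis=1))
    return H[sorted(chosen)]


# ---------------------------------------------------------------------------
# per-partition disk spill (map-reduce contract)


def write_confidence_table(cohort: CohortGenotypes, path: str) -> None:
    """Spill per-call confidences to a TSV (locus, sample, call,
    confidence) so partitions can be genotyped on separate nodes and
    aggregated later from their spill files."""
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tsample\tcall\tconfidence\n")
        for l, locus in enumerate(cohort.panel.loci):
            for s, sid in enumerate(cohort.sample_ids):
                gt = cohort.genotypes[l, s]
                call = "./." if gt[0] < 0 else f"{gt[0]}/{gt[1]}"
                fh.write(
                    f"{locus.chrom}\t{locus.pos}\t{sid}\t{call}\t"
                    f"{cohort.confidence[l, s]:.6f}\n"
                )


def read_confidence_table(path: str):
    """Read a confidence spill file back as a pandas DataFrame."""
    import pandas as pd

    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# 2-pass workflow


def two_pass(
    panel: VariantPanel,
    indexes: list,
    config: RefinerConfig | None = None,
    hmm: HMMParams | None = None,
    panel_haplotypes: int = DEFAULT_PANEL_HAPLOTYPES,
    log: list | None = None,
) -> CohortGenotypes:
    """Genotype and phase unphased variants with population feedback.

    Pass 1 genotypes every partition with emissions only, filters on
    the per-locus median confidence, imputes and phases; the phased
    cohort haplotypes (subsampled for tractability) become the
    reference panel of pass 2, which re-genotypes every partition with
    the Li-Stephens HMM and refines again.  A pre-phased input panel
    skips pass 1.
    """
    config = config or RefinerConfig()
    hmm = hmm or HMMParams(rho=config.rho)
    if log is None:
        log = []

    def stage(name, **info):
        log.append({"stage": name, **info})

    if panel.phased:
        stage("pass1_skipped", reason="input panel already phased")
        hmm_panel = panel
    else:
        parts = [
            genotype_partition(panel, idx, mode="kmer") for idx in indexes
        ]
        stage("genotype_pass1", mode="kmer", partitions=len(parts))
        cohort = aggregate_partitions(parts)
        stage("aggregate_pass1", samples=cohort.n_samples)
        cohort, report = median_confidence_filter(cohort)
        stage("filter_pass1", filtered=int(report.filtered.sum()))
        cohort = impute_missing(cohort, panel, config)
        stage("impute_pass1")
        phased_panel = phase_cohort(cohort, panel, config)
        stage("phase_pass1", haplotypes=phased_panel.n_haplotypes)
        haps = subsample_haplotypes(phased_panel.haplotypes, panel_haplotypes)
        hmm_panel = panel.with_haplotypes(haps)
        stage("subsample_panel", haplotypes=int(haps.shape[0]))

    parts = [
        genotype_partition(hmm_panel, idx, mode="hmm", hmm=hmm)
        for idx in indexes
    ]
    stage("genotype_pass2", mode="hmm", partitions=len(parts))
    cohort = aggregate_partitions(parts)
    stage("aggregate_pass2", samples=cohort.n_samples)
    cohort, report = median_confidence_filter(cohort)
    stage("filter_pass2", filtered=int(report.filtered.sum()))
    cohort = impute_missing(cohort, panel, config)
    stage("impute_pass2")
    phase_cohort(cohort, hmm_panel, config)
    stage("phase_pass2")
    return cohort


# ---------------------------------------------------------------------------
# external refiner hook


def _external_refine(
    cohort: CohortGenotypes, config: RefinerConfig, phase: bool
) -> CohortGenotypes:
    """Round-trip the cohort through a user command (e.g. an external
    statistical imputation/phasing tool).

    The command template receives {in_vcf} and {out_vcf}; the returned
    VCF must cover the same loci and samples.
    """
    from . import vcfio

    with tempfile.TemporaryDirectory(prefix="popccdg_refine_") as tmp:
        in_vcf = f"{tmp}/in.vcf"
        out_vcf = f"{tmp}/out.vcf"
        vcfio.write_cohort_vcf(cohort, in_vcf)
        cmd = config.command_template.format(in_vcf=in_vcf, out_vcf=out_vcf)
        proc = subprocess.run(
            shlex.split(cmd), capture_output=True, text=True
        )
        if proc.returncode != 0:
            raise RefinerError(
                f"external refiner failed (exit {proc.returncode}): "
                f"{proc.stderr.strip()}"
            )
        try:
            keys, samples, gts = vcfio.read_genotypes(out_vcf)
        except Exception as e:
            raise RefinerError(f"malformed refiner output VCF: {e}") from e
    expected = [
        (l.chrom, l.pos, l.ref_allele, tuple(l.alt_alleles))
        for l in cohort.panel.loci
    ]
    if keys != expected or samples != cohort.sample_ids:
        raise RefinerError(
            "refiner output VCF does not match input loci/samples"
        )
    out = _clone(cohort)
    was_missing = cohort.missing_mask()
    order = np.sort(gts, axis=2)
    out.genotypes = order.astype(np.int8)
    out.flags[was_missing] |= FLAG_IMPUTED
    if phase:
        n = out.n_samples
        haps = np.zeros((2 * n, out.n_loci), dtype=np.int8)
        for s in range(n):
            haps[2 * s] = gts[:, s, 0]
            haps[2 * s + 1] = gts[:, s, 1]
        out.haplotypes = haps
    return out
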