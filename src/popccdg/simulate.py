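"""Seeded simulator: reference, founder haplotypes, recombinant diploid
cohorts with LD structure, and error-bearing short reads.

The generator mirrors the structure of a haplotype-resolved truth set:
variants are placed on a small set of founder haplotypes, each cohort
sample is a diploid pair of founder mosaics (crossovers drawn as a
Poisson process), and reads are sampled uniformly from both haplotypes
with independent substitution errors.  Everything is deterministic per
seed, so truth genotypes, phased truth haplotypes, and reads are
exactly consistent with each other.
"""

from __future__ import annotations

import gzip
import os
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = np.zeros(256, dtype=np.uint8)
for a, b in zip(b"ACGT", b"TGCA"):
    _COMP[a] = b


@dataclass
class SimConfig:
    ref_length: int = 300_000
    gc: float = 0.41  # human-like base composition
    n_founders: int = 8  # founder haplotypes
    n_snp: int = 400
    n_small_indel: int = 60
    n_sv_indel: int = 25
    sv_size_range: tuple[int, int] = (50, 500)
    n_complex: int = 0
    n_samples: int = 25
    recomb_rate: float = 1e-5  # crossovers per bp per haplotype
    depth: float = 30.0
    read_length: int = 100
    error_rate: float = 0.002
    seed: int = 0
    min_variant_gap: int = 70  # bp between reference spans of edits

    def __post_init__(self):
        for name in (
            "n_snp", "n_small_indel", "n_sv_indel", "n_complex",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.recomb_rate < 0 or self.error_rate < 0:
            raise ValidationError("rates must be >= 0")
        if self.seed is None:
            raise ValidationError("seed is mandatory")


@dataclass
class SimVariant:
    pos: int  # 1-based, VCF convention (anchor base included for indels)
    ref: str
    alt: str
    var_class: str


@dataclass
class FounderSet:
    chrom: str
    reference: str
    variants: list[SimVariant]
    # (n_founder_haplotypes, n_variants) 0/1 allele matrix
    alleles: np.ndarray


@dataclass
class TruthSet:
    config: SimConfig
    chrom: str
    reference: str
    founders: FounderSet
    # per haplotype (2 per sample): list of (start, end, founder) segments
    mosaics: list[list[tuple[int, int, int]]]
    # (n_variants, n_samples, 2) phased truth allele indices
    genotypes: np.ndarray
    sample_ids: list[str]

    @property
    def n_variants(self) -> int:
        return self.genotypes.shape[0]

    def haplotype_alleles(self, hap: int) -> np.ndarray:
        s, which = divmod(hap, 2)
        return self.genotypes[:, s, which]

    def haplotype_sequence(self, hap: int) -> str:
        return apply_variants(
            self.reference,
            self.founders.variants,
            self.haplotype_alleles(hap),
        )


def _rng(seed: int, *stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, *stream)))


def simulate_reference(cfg: SimConfig, chrom: str = "chrSim") -> str:
    """I.i.d. reference sequence at the configured GC content."""
    rng = _rng(cfg.seed, 1)
    p_gc = cfg.gc / 2.0
    p_at = (1.0 - cfg.gc) / 2.0
    codes = rng.choice(4, size=cfg.ref_length, p=[p_at, p_gc, p_gc, p_at])
    return _BASES[codes].tobytes().decode("ascii")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def simulate_founders(
    reference: str, cfg: SimConfig, chrom: str = "chrSim"
) -> FounderSet:
    """Place variants on founder haplotypes.

    SNPs, insertions/deletions below and at/above the 50-bp structural
    threshold, and complex multi-base substitutions are placed at
    non-overlapping positions (rejection-sampled with a minimum gap);
    each variant's founder carrier count is drawn uniformly, giving a
    spread of marginal allele frequencies.
    """
    rng = _rng(cfg.seed, 2)
    L = len(reference)
    specs = (
        [("snp", None)] * cfg.n_snp
        + [("small_indel", None)] * cfg.n_small_indel
        + [("sv_indel", cfg.sv_size_range)] * cfg.n_sv_indel
        + [("complex", None)] * cfg.n_complex
    )
    taken: list[tuple[int, int]] = []  # 0-based [start, end) spans, sorted

    def reserve(start: int, end: int) -> bool:
        for s, e in taken:
            if start < e + cfg.min_variant_gap and s < end + cfg.min_variant_gap:
                return False
        taken.append((start, end))
        return True

    variants: list[SimVariant] = []
    for kind, size_range in specs:
        placed = False
        for _ in range(2000):
            if kind == "snp":
                span = 1
            elif kind == "small_indel":
                size = int(rng.integers(1, 50))
                deletion = bool(rng.integers(0, 2))
                span = 1 + size if deletion else 1
            elif kind == "sv_indel":
                size = int(rng.integers(size_range[0], size_range[1] + 1))
                deletion = bool(rng.integers(0, 2))
                span = 1 + size if deletion else 1
            else:  # complex: replace a >=2 bp segment by a different one
                del_len = int(rng.integers(3, 13))
                ins_len = int(rng.integers(3, 13))
                span = del_len
            start = int(rng.integers(1, L - span - 1))
            if not reserve(start, start + span):
                continue
            if kind == "snp":
                ref = reference[start]
                alt = "ACGT"[("ACGT".index(ref) + int(rng.integers(1, 4))) % 4]
            elif kind in ("small_indel", "sv_indel"):
                if deletion:
                    ref = reference[start : start + 1 + size]
                    alt = reference[start]
                else:
                    ref = reference[start]
                    alt = ref + _random_seq(rng, size)
            else:
                ref = reference[start : start + del_len]
                alt = _random_seq(rng, ins_len)
                if alt == ref or alt[0] == ref[0]:
                    # keep both breakpoints distinct from the reference
                    alt = (
                        "ACGT"[("ACGT".index(ref[0]) + 1) % 4] + alt[1:]
                    )
            variants.append(SimVariant(start + 1, ref, alt, kind))
            placed = True
            break
        if not placed:
            raise ValidationError(
                "variant density too high to place without overlap"
            )
    variants.sort(key=lambda v: v.pos)

    n_haps = cfg.n_founders
    alleles = np.zeros((n_haps, len(variants)), dtype=np.int8)
    for j in range(len(variants)):
        n_carriers = int(rng.integers(1, n_haps))  # 1 .. n_haps-1
        carriers = rng.choice(n_haps, size=n_carriers, replace=False)
        alleles[carriers, j] = 1
    return FounderSet(
        chrom=chrom, reference=reference, variants=variants, alleles=alleles
    )


def apply_variants(
    reference: str, variants: list[SimVariant], alleles: np.ndarray
) -> str:
    """Haplotype sequence: apply the carried (non-overlapping) edits."""
    seq = reference
    for v, a in sorted(
        zip(variants, alleles), key=lambda t: -t[0].pos
    ):
        if a > 0:
            s = v.pos - 1
            seq = seq[:s] + v.alt + seq[s + len(v.ref) :]
    return seq


def simulate_cohort(
    founders: FounderSet, cfg: SimConfig
) -> TruthSet:
    """Recombinant diploid cohort from the founder haplotypes.

    Every sample haplotype is a founder mosaic: crossover points are a
    Poisson process at ``recomb_rate`` per bp, and each segment copies
    one founder (switches always move to a different founder).  Truth
    genotypes are read off the mosaics exactly.
    """
    if cfg.n_founders < 2:
        raise ValidationError("need at least 2 founder haplotypes")
    rng = _rng(cfg.seed, 3)
    L = len(founders.reference)
    positions = np.array([v.pos - 1 for v in founders.variants])
    n_variants = len(founders.variants)
    mosaics: list[list[tuple[int, int, int]]] = []
    genotypes = np.zeros((n_variants, cfg.n_samples, 2), dtype=np.int8)
    for s in range(cfg.n_samples):
        for which in (0, 1):
            n_cross = rng.poisson(cfg.recomb_rate * L)
            cuts = np.sort(rng.integers(1, L, size=n_cross)) if n_cross else []
            bounds = [0, *[int(c) for c in cuts], L]
            founder = int(rng.integers(0, cfg.n_founders))
            segments = []
            for lo, hi in zip(bounds[:-1], bounds[1:]):
                segments.append((lo, hi, founder))
                if cfg.n_founders > 1:
                    step = int(rng.integers(1, cfg.n_founders))
                    founder = (founder + step) % cfg.n_founders
            mosaics.append(segments)
            for lo, hi, f in segments:
                in_seg = (positions >= lo) & (positions < hi)
                genotypes[in_seg, s, which] = founders.alleles[f, in_seg]
    sample_ids = [f"sample{s:03d}" for s in range(cfg.n_samples)]
    return TruthSet(
        config=cfg,
        chrom=founders.chrom,
        reference=founders.reference,
        founders=founders,
        mosaics=mosaics,
        genotypes=genotypes,
        sample_ids=sample_ids,
    )


def simulate_reads(
    haplotypes: tuple[str, str],
    cfg: SimConfig,
    seed: int,
) -> list[str]:
    """Uniform short reads from a diploid genome with substitution
    errors; deterministic per seed."""
    if cfg.depth <= 0:
        raise ValidationError("depth must be > 0")
    rng = _rng(seed, 4)
    reads: list[str] = []
    for hap in haplotypes:
        L = len(hap)
        if cfg.read_length > L:
            raise ValidationError("read_length exceeds genome length")
        n_reads = int(round(cfg.depth / 2.0 * L / cfg.read_length))
        starts = rng.integers(0, L - cfg.read_length + 1, size=n_reads)
        arr = np.frombuffer(hap.encode("ascii"), dtype=np.uint8)
        mat = arr[starts[:, None] + np.arange(cfg.read_length)[None, :]].copy()
        if cfg.error_rate > 0:
            err = rng.random(mat.shape) < cfg.error_rate
            if err.any():
                code_of = np.zeros(256, dtype=np.uint8)
                for i, b in enumerate(_BASES):
                    code_of[b] = i
                c = code_of[mat[err]]
                shift = rng.integers(1, 4, size=c.size).astype(np.uint8)
                mat[err] = _BASES[(c + shift) % 4]
        flip = rng.random(n_reads) < 0.5
        for i in range(n_reads):
            row = mat[i]
            if flip[i]:
                row = _COMP[row][::-1]
            reads.append(row.tobytes().decode("ascii"))
    return reads


# ---------------------------------------------------------------------------
# on-disk truth set


def write_fasta(path: str, chrom: str, sequence: str, width: int = 80) -> None:
    with open(path, "w") as fh:
        fh.write(f">{chrom}\n")
        for i in range(0, len(sequence), width):
            fh.write(sequence[i : i + width] + "\n")


def write_fastq(path: str, reads: list[str], prefix: str = "read") -> None:
    op = gzip.open if os.fspath(path).endswith(".gz") else open
    with op(path, "wt") as fh:
        for i, seq in enumerate(reads):
            fh.write(f"@{prefix}_{i}\n{seq}\n+\n{'I' * len(seq)}\n")


def _vcf_header(chrom: str, length: int, sample_names: list[str]) -> str:
    cols = "\t".join(sample_names)
    return (
        "##fileformat=VCFv4.2\n"
        f"##contig=<ID={chrom},length={length}>\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + cols + "\n"
    )


def write_founder_vcf(founders: FounderSet, path: str) -> None:
    """Phased founder VCF; founder haplotypes are paired into diploid
    pseudo-samples (f0|f1, f2|f3, ...)."""
    n_haps = founders.alleles.shape[0]
    if n_haps % 2:
        raise ValidationError("founder haplotype count must be even for VCF")
    names = [f"founder{i:02d}" for i in range(n_haps // 2)]
    with open(path, "w") as fh:
        fh.write(_vcf_header(founders.chrom, len(founders.reference), names))
        for j, v in enumerate(founders.variants):
            gts = "\t".join(
                f"{founders.alleles[2 * i, j]}|{founders.alleles[2 * i + 1, j]}"
                for i in range(n_haps // 2)
            )
            fh.write(
                f"{founders.chrom}\t{v.pos}\tvar{j:05d}\t{v.ref}\t{v.alt}"
                f"\t.\tPASS\t.\tGT\t{gts}\n"
            )


def write_unphased_vcf(founders: FounderSet, path: str) -> None:
    """Site-only unphased VCF of the founder variants (no samples)."""
    with open(path, "w") as fh:
        fh.write(
            "##fileformat=VCFv4.2\n"
            f"##contig=<ID={founders.chrom},length={len(founders.reference)}>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
        )
        for j, v in enumerate(founders.variants):
            fh.write(
                f"{founders.chrom}\t{v.pos}\tvar{j:05d}\t{v.ref}\t{v.alt}"
                f"\t.\tPASS\t.\n"
            )


def write_truth_vcf(truth: TruthSet, path: str, phased: bool = True) -> None:
    """Truth genotypes of the cohort samples over the founder variants."""
    sep = "|" if phased else "/"
    with open(path, "w") as fh:
        fh.write(_vcf_header(truth.chrom, len(truth.reference), truth.sample_ids))
        for j, v in enumerate(truth.founders.variants):
            gts = []
            for s in range(len(truth.sample_ids)):
                a, b = truth.genotypes[j, s]
                if not phased:
                    a, b = sorted((a, b))
                gts.append(f"{a}{sep}{b}")
            fh.write(
                f"{truth.chrom}\t{v.pos}\tvar{j:05d}\t{v.ref}\t{v.alt}"
                f"\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def write_truth_genotypes_tsv(truth: TruthSet, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("variant\tpos\t" + "\t".join(truth.sample_ids) + "\n")
        for j, v in enumerate(truth.founders.variants):
            row = [
                f"{truth.genotypes[j, s, 0]}|{truth.genotypes[j, s, 1]}"
                for s in range(len(truth.sample_ids))
            ]
            fh.write(f"var{j:05d}\t{v.pos}\t" + "\t".join(row) + "\n")
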