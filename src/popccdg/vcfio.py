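"""VCF input/output for cohort genotypes (pysam-backed).

Output carries INFO AF/AC/AN and per-sample FORMAT fields GT, GQ
(Phred-scaled from 1 - p_top, capped at 99), CF (confidence, the
top-minus-second posterior difference), KC (summed allele k-mer
counts) and FT (call-level flags).  Headers are timestamp-free so a
seeded rerun is byte-identical.
"""

from __future__ import annotations

import math
import os

import numpy as np
import pysam

from .errors import ValidationError
from .genotype import (
    FLAG_FILTERED,
    FLAG_IMPUTED,
    FLAG_UNINFORMATIVE,
    CohortGenotypes,
)

_FLAG_NAMES = [
    (FLAG_FILTERED, "FILTERED"),
    (FLAG_IMPUTED, "IMPUTED"),
    (FLAG_UNINFORMATIVE, "UNINF"),
]


def _flag_string(flags: int) -> str:
    names = [name for bit, name in _FLAG_NAMES if flags & bit]
    return "+".join(names) if names else "PASS"


def _gq_from_posterior(p_top: float) -> int:
    if p_top >= 1.0:
        return 99
    return min(99, int(round(-10.0 * math.log10(max(1.0 - p_top, 1e-10)))))


def write_cohort_vcf(
    cohort: CohortGenotypes,
    path: str,
    phased: bool = False,
    extra_meta: dict | None = None,
) -> None:
    """Write a multi-sample VCF for a cohort.

    When ``phased`` and the cohort carries haplotypes, GT uses the '|'
    separator with the phased allele order; otherwise genotypes are
    written unphased (sorted allele pair).
    """
    panel = cohort.panel
    header = pysam.VariantHeader()
    for line in [
        '##INFO=<ID=AF,Number=A,Type=Float,Description="Alternate allele frequency among non-missing calls">',
        '##INFO=<ID=AC,Number=A,Type=Integer,Description="Alternate allele count">',
        '##INFO=<ID=AN,Number=1,Type=Integer,Description="Number of non-missing alleles">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Phred-scaled genotype quality from 1-p_top, capped at 99">',
        '##FORMAT=<ID=CF,Number=1,Type=Float,Description="Genotype confidence: top minus second posterior">',
        '##FORMAT=<ID=KC,Number=1,Type=Integer,Description="Summed allele-unique k-mer counts">',
        '##FORMAT=<ID=FT,Number=1,Type=String,Description="Call flags: PASS, FILTERED, IMPUTED, UNINF">',
    ]:
        header.add_line(line)
    for meta_key, meta_val in (extra_meta or {}).items():
        header.add_line(f"##{meta_key}={meta_val}")
    contigs = panel.contig_lengths or {}
    seen = set()
    for locus in panel.loci:
        if locus.chrom not in seen:
            seen.add(locus.chrom)
            length = contigs.get(locus.chrom)
            if length:
                header.add_line(f"##contig=<ID={locus.chrom},length={length}>")
            else:
                header.add_line(f"##contig=<ID={locus.chrom}>")
    for sid in cohort.sample_ids:
        header.add_sample(sid)

    with pysam.VariantFile(os.fspath(path), "w", header=header) as out:
        for l, locus in enumerate(panel.loci):
            rec = out.new_record(
                contig=locus.chrom,
                start=locus.start,
                stop=locus.end,
                alleles=tuple(locus.alleles),
            )
            n_alts = len(locus.alt_alleles)
            an = 0
            ac = np.zeros(n_alts, dtype=np.int64)
            for s in range(cohort.n_samples):
                gt = cohort.genotypes[l, s]
                if gt[0] >= 0:
                    an += 2
                    for a in gt:
                        if a > 0:
                            ac[a - 1] += 1
            rec.info["AN"] = an
            rec.info["AC"] = tuple(int(x) for x in ac)
            if an > 0:
                rec.info["AF"] = tuple(float(x) / an for x in ac)
            for s, sid in enumerate(cohort.sample_ids):
                gt = cohort.genotypes[l, s]
                sample = rec.samples[sid]
                if gt[0] < 0:
                    sample["GT"] = (None, None)
                else:
                    if phased and cohort.haplotypes is not None:
                        pair = (
                            int(cohort.haplotypes[2 * s, l]),
                            int(cohort.haplotypes[2 * s + 1, l]),
                        )
                    else:
                        pair = (int(gt[0]), int(gt[1]))
                    sample["GT"] = pair
                    sample.phased = bool(phased and cohort.haplotypes is not None)
                call = cohort.call(l, s)
                p_top = float(call.posteriors.max())
                sample["GQ"] = _gq_from_posterior(p_top)
                sample["CF"] = float(cohort.confidence[l, s])
                if cohort.kmer_totals is not None:
                    sample["KC"] = int(cohort.kmer_totals[l, s])
                sample["FT"] = _flag_string(int(cohort.flags[l, s]))
            out.write(rec)


def read_genotypes(path: str):
    """Read GT fields of a VCF.

    Returns (loci_keys, sample_ids, genotypes) where ``loci_keys`` are
    (chrom, pos, ref, alts) tuples and genotypes is an
    (n_loci, n_samples, 2) int array with -1 for missing alleles.
    """
    keys = []
    gts = []
    with pysam.VariantFile(os.fspath(path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            keys.append((rec.chrom, rec.pos, rec.ref, tuple(rec.alts or ())))
            row = []
            for sid in samples:
                alleles = rec.samples[sid]["GT"]
                if alleles is None or len(alleles) == 0:
                    row.append((-1, -1))
                else:
                    if len(alleles) == 1:
                        alleles = (alleles[0], alleles[0])
                    row.append(
                        tuple(-1 if a is None else int(a) for a in alleles)
                    )
            gts.append(row)
    genotypes = (
        np.array(gts, dtype=np.int64)
        if gts
        else np.zeros((0, len(samples), 2), dtype=np.int64)
    )
    return keys, samples, genotypes
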