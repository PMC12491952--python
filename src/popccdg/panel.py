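"""Variant panel preparation: from VCF + reference to genotypable loci.

Overlapping phased records are merged into one multi-allelic locus whose
alternative alleles are the distinct local haplotype strings observed in
the panel; every allele then gets a flanked sequence and a set of
k-mers that occur exactly once in a global census over the reference
plus all alternative allele sequences.  Those allele-unique k-mers are
the evidence units the genotyper counts in the population index.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pysam
from pyfaidx import Fasta

from . import kmers as km
from .errors import ConfigurationError, ConsistencyError, ValidationError

DEFAULT_KMER_CAP = 300  # per-allele bound on emitted unique k-mers
SV_SIZE = 50  # bp; indels at or above are structural


class VarClass(str, Enum):
    snp = "snp"
    small_indel = "small_indel"
    sv_indel = "sv_indel"
    complex = "complex"


@dataclass
class VariantLocus:
    chrom: str
    pos: int  # 1-based, VCF convention
    ref_allele: str
    alt_alleles: list[str]
    var_class: VarClass
    source_ids: list[str] = field(default_factory=list)

    @property
    def start(self) -> int:
        """0-based start."""
        return self.pos - 1

    @property
    def end(self) -> int:
        """0-based half-open end of the reference span."""
        return self.pos - 1 + len(self.ref_allele)

    @property
    def alleles(self) -> list[str]:
        return [self.ref_allele, *self.alt_alleles]

    @property
    def n_alleles(self) -> int:
        return 1 + len(self.alt_alleles)


@dataclass
class VariantPanel:
    loci: list[VariantLocus]
    k: int
    flank: int
    haplotypes: np.ndarray | None = None  # (n_haplotypes, n_loci) allele idx
    haplotype_names: list[str] | None = None
    allele_kmers: list[list[np.ndarray]] | None = None  # [locus][allele]
    contig_lengths: dict[str, int] = field(default_factory=dict)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def phased(self) -> bool:
        return self.haplotypes is not None

    @property
    def n_haplotypes(self) -> int:
        return 0 if self.haplotypes is None else self.haplotypes.shape[0]

    def uninformative_mask(self) -> np.ndarray:
        """True where no allele of the locus has any unique k-mer."""
        if self.allele_kmers is None:
            raise ValidationError("unique k-mers not extracted yet")
        return np.array(
            [all(a.size == 0 for a in per_locus) for per_locus in self.allele_kmers]
        )

    def with_haplotypes(
        self, haplotypes: np.ndarray, names: list[str] | None = None
    ) -> "VariantPanel":
        return VariantPanel(
            loci=self.loci,
            k=self.k,
            flank=self.flank,
            haplotypes=np.asarray(haplotypes, dtype=np.int8),
            haplotype_names=names,
            allele_kmers=self.allele_kmers,
            contig_lengths=self.contig_lengths,
        )


def classify_variant(ref: str, alts: list[str]) -> VarClass:
    """Variant class from allele lengths.

    SNP: 1 bp -> 1 bp substitution.  Pure insertions/deletions (one
    allele is a prefix anchor) are small below 50 bp of length change
    and structural at or above.  Multi-base substitutions, or records
    with both inserted and deleted content, are complex (they create
    more than one breakpoint).  Multi-allelic loci take the most severe
    class across alternatives (complex > sv_indel > small_indel > snp).
    """
    order = [VarClass.snp, VarClass.small_indel, VarClass.sv_indel, VarClass.complex]

    def one(alt: str) -> VarClass:
        if len(ref) == 1 and len(alt) == 1:
            return VarClass.snp
        if len(ref) == 1 or len(alt) == 1:
            size = abs(len(ref) - len(alt))
            return VarClass.small_indel if size < SV_SIZE else VarClass.sv_indel
        return VarClass.complex

    return max((one(a) for a in alts), key=order.index)


def _check_allele(a: str, where: str) -> str:
    a = a.upper()
    if not a or any(c not in "ACGT" for c in a):
        raise ValidationError(
            f"non-ACGT or symbolic allele {a!r} at {where}; "
            "sequence-resolved alleles only"
        )
    return a


def _open_reference(reference) -> Fasta:
    if isinstance(reference, Fasta):
        return reference
    return Fasta(os.fspath(reference), as_raw=True, sequence_always_upper=True)


def load_panel(
    vcf,
    reference,
    k: int = 31,
    flank: int | None = None,
) -> VariantPanel:
    """Read a sorted VCF into a panel of merged, non-overlapping loci.

    Phased multi-sample input yields a haplotype matrix (two haplotypes
    per diploid sample, GT separator '|'); overlapping phased records
    are merged into one locus by enumerating the distinct local
    haplotype strings.  Overlapping unphased records are rejected.
    """
    if flank is None:
        flank = 2 * (k - 1)
    if flank < k - 1:
        raise ConfigurationError(f"flank must be >= k-1 ({k - 1}), got {flank}")
    ref = _open_reference(reference)

    records: list[dict] = []
    with pysam.VariantFile(os.fspath(vcf)) as vf:
        sample_names = list(vf.header.samples)
        last = {}
        for rec in vf:
            if rec.chrom not in ref:
                raise ConsistencyError(f"contig {rec.chrom} absent from reference")
            if rec.chrom in last and rec.pos < last[rec.chrom]:
                raise ValidationError(
                    f"VCF not sorted at {rec.chrom}:{rec.pos}"
                )
            last[rec.chrom] = rec.pos
            ref_allele = _check_allele(rec.ref, f"{rec.chrom}:{rec.pos}")
            alts = [
                _check_allele(a, f"{rec.chrom}:{rec.pos}")
                for a in (rec.alts or [])
            ]
            ref_seq = str(ref[rec.chrom][rec.start : rec.start + len(ref_allele)])
            if ref_seq.upper() != ref_allele:
                raise ConsistencyError(
                    f"REF mismatch at {rec.chrom}:{rec.pos}: "
                    f"VCF {ref_allele!r} vs reference {ref_seq!r}"
                )
            gts, phased = [], True
            for name in sample_names:
                call = rec.samples[name]
                alleles = call["GT"]
                if alleles is None or any(a is None for a in alleles):
                    raise ValidationError(
                        f"missing GT for {name} at {rec.chrom}:{rec.pos}"
                    )
                if len(alleles) == 1:
                    alleles = (alleles[0], alleles[0])
                elif not call.phased:
                    phased = False
                gts.append(tuple(int(a) for a in alleles))
            records.append(
                dict(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=ref_allele,
                    alts=alts,
                    gts=gts,
                    phased=phased,
                    id=rec.id or f"{rec.chrom}:{rec.pos}",
                )
            )

    all_phased = bool(records) and all(r["phased"] for r in records) and sample_names
    loci: list[VariantLocus] = []
    hap_cols: list[list[int]] = []
    n_haps = 2 * len(sample_names)

    # group overlapping records per chromosome
    groups: list[list[dict]] = []
    for r in records:
        if (
            groups
            and groups[-1][-1]["chrom"] == r["chrom"]
            and r["pos"] - 1 < max(g["pos"] - 1 + len(g["ref"]) for g in groups[-1])
        ):
            groups[-1].append(r)
        else:
            groups.append([r])

    for group in groups:
        if len(group) == 1:
            r = group[0]
            loci.append(
                VariantLocus(
                    chrom=r["chrom"],
                    pos=r["pos"],
                    ref_allele=r["ref"],
                    alt_alleles=list(r["alts"]),
                    var_class=classify_variant(r["ref"], r["alts"]),
                    source_ids=[r["id"]],
                )
            )
            if all_phased:
                col = []
                for gt in r["gts"]:
                    col.extend(gt)
                hap_cols.append(col)
            continue
        if not all_phased:
            positions = ", ".join(f"{g['chrom']}:{g['pos']}" for g in group)
            raise ValidationError(
                f"overlapping unphased records cannot be merged: {positions}"
            )
        loci_entry, col = _merge_group(group, ref, n_haps)
        loci.append(loci_entry)
        hap_cols.append(col)

    haplotypes = None
    names = None
    if all_phased:
        haplotypes = np.array(hap_cols, dtype=np.int8).T
        names = [f"{s}_h{i}" for s in sample_names for i in (1, 2)]
    return VariantPanel(
        loci=loci,
        k=k,
        flank=flank,
        haplotypes=haplotypes,
        haplotype_names=names,
        contig_lengths={c: len(ref[c]) for c in ref.keys()},
    )


def _merge_group(group: list[dict], ref: Fasta, n_haps: int):
    """Merge overlapping phased records into one multi-allelic locus."""
    chrom = group[0]["chrom"]
    start = min(g["pos"] - 1 for g in group)
    end = max(g["pos"] - 1 + len(g["ref"]) for g in group)
    span_ref = str(ref[chrom][start:end]).upper()
    hap_strings: list[str] = []
    for h in range(n_haps):
        edits = []
        for g in group:
            allele_idx = g["gts"][h // 2][h % 2]
            if allele_idx > 0:
                s = g["pos"] - 1 - start
                edits.append((s, s + len(g["ref"]), g["alts"][allele_idx - 1]))
        edits.sort()
        for (s1, e1, _), (s2, _, _) in zip(edits, edits[1:]):
            if s2 < e1:
                raise ValidationError(
                    f"conflicting overlapping alleles on one haplotype near "
                    f"{chrom}:{start + 1}"
                )
        seq = span_ref
        for s, e, alt in reversed(edits):
            seq = seq[:s] + alt + seq[e:]
        hap_strings.append(seq)
    alts: list[str] = []
    col: list[int] = []
    for seq in hap_strings:
        if seq == span_ref:
            col.append(0)
        else:
            if seq not in alts:
                alts.append(seq)
            col.append(1 + alts.index(seq))
    locus = VariantLocus(
        chrom=chrom,
        pos=start + 1,
        ref_allele=span_ref,
        alt_alleles=alts,
        var_class=classify_variant(span_ref, alts) if alts else VarClass.snp,
        source_ids=[g["id"] for g in group],
    )
    return locus, col


def allele_sequence(
    locus: VariantLocus, reference, flank: int
) -> list[str]:
    """Flanked sequence of every allele (reference allele first).

    ``flank`` reference bases on each side with the allele substituted,
    truncated at contig ends.
    """
    ref = _open_reference(reference)
    if locus.chrom not in ref:
        raise ConsistencyError(f"contig {locus.chrom} absent from reference")
    contig = ref[locus.chrom]
    if locus.end > len(contig):
        raise ConsistencyError(
            f"locus {locus.chrom}:{locus.pos} extends past contig end"
        )
    left = str(contig[max(0, locus.start - flank) : locus.start]).upper()
    right = str(contig[locus.end : locus.end + flank]).upper()
    return [left + allele + right for allele in locus.alleles]


def extract_unique_kmers(
    panel: VariantPanel,
    reference,
    cap: int = DEFAULT_KMER_CAP,
) -> VariantPanel:
    """Attach to each allele the k-mers that identify it genome-wide.

    A census counts every canonical k-mer's occurrences across the full
    reference plus all alternative allele sequences (the reference
    allele's occurrence is already counted by the reference itself).  A
    k-mer is kept for an allele iff its census count is exactly 1 and
    its window lies within ``panel.flank`` bases of the allele's edit;
    k-mers claimed by more than one allele are dropped, and at most
    ``cap`` k-mers are kept per allele, closest to the edit first.
    Alleles may end with zero k-mers; loci where every allele has zero
    are uninformative and will be imputed rather than measured.
    """
    k, flank = panel.k, panel.flank
    if k > km.MAX_PACKED_K:
        raise ConfigurationError(
            f"unique k-mer extraction supports k <= {km.MAX_PACKED_K}, got {k}"
        )
    ref = _open_reference(reference)

    census_parts = [
        km.canonical_kmers_packed(str(ref[c][:]), k) for c in ref.keys()
    ]
    allele_seqs: list[list[str]] = []
    for locus in panel.loci:
        seqs = allele_sequence(locus, ref, flank)
        allele_seqs.append(seqs)
        for alt_seq in seqs[1:]:
            census_parts.append(km.canonical_kmers_packed(alt_seq, k))
    census_keys, census_counts = km.aggregate_counts(
        np.concatenate([p for p in census_parts if p.size])
    )

    def census_of(arr: np.ndarray) -> np.ndarray:
        idx = np.clip(np.searchsorted(census_keys, arr), 0, census_keys.size - 1)
        out = np.where(census_keys[idx] == arr, census_counts[idx], 0)
        return out

    # first pass: census-unique candidates per allele, with distances
    candidates: list[list[tuple[np.ndarray, np.ndarray]]] = []
    claim_parts: list[np.ndarray] = []
    for locus, seqs in zip(panel.loci, allele_seqs):
        left_len = locus.start - max(0, locus.start - flank)
        per_allele = []
        for allele, seq in zip(locus.alleles, seqs):
            arr = km.canonical_kmers_packed(seq, k)
            if arr.size == 0:
                per_allele.append((arr, np.empty(0, dtype=np.int64)))
                continue
            edit_start, edit_end = left_len, left_len + len(allele)
            starts = np.arange(arr.size)
            ends = starts + k  # half-open window end
            dist = np.maximum(
                0, np.maximum(edit_start - ends + 1, starts - edit_end + 1)
            )
            keep = (dist <= flank) & (census_of(arr) == 1)
            kept, dist_kept = arr[keep], dist[keep]
            # a k-mer may appear at several positions in one allele
            # sequence only if census > 1, so kept entries are distinct
            per_allele.append((kept, dist_kept))
            claim_parts.append(kept)
        candidates.append(per_allele)

    if claim_parts:
        claim_keys, claim_counts = km.aggregate_counts(np.concatenate(claim_parts))
        multi = claim_keys[claim_counts > 1]
    else:
        multi = np.empty(0, dtype=np.uint64)

    allele_kmers: list[list[np.ndarray]] = []
    for per_allele in candidates:
        out = []
        for kept, dist in per_allele:
            if kept.size and multi.size:
                ok = ~np.isin(kept, multi)
                kept, dist = kept[ok], dist[ok]
            order = np.lexsort((kept, dist))[:cap]
            out.append(kept[np.sort(order)])
        allele_kmers.append(out)

    return VariantPanel(
        loci=panel.loci,
        k=k,
        flank=flank,
        haplotypes=panel.haplotypes,
        haplotype_names=panel.haplotype_names,
        allele_kmers=allele_kmers,
        contig_lengths={c: len(ref[c]) for c in ref.keys()},
    )


# ---------------------------------------------------------------------------
# serialization for reuse alongside the index


def save_panel(panel: VariantPanel, path: str) -> None:
    doc = {
        "k": panel.k,
        "flank": panel.flank,
        "contig_lengths": panel.contig_lengths,
        "loci": [
            {
                "chrom": l.chrom,
                "pos": l.pos,
                "ref": l.ref_allele,
                "alts": l.alt_alleles,
                "class": l.var_class.value,
                "source_ids": l.source_ids,
            }
            for l in panel.loci
        ],
        "haplotypes": (
            None if panel.haplotypes is None else panel.haplotypes.tolist()
        ),
        "haplotype_names": panel.haplotype_names,
        "allele_kmers": (
            None
            if panel.allele_kmers is None
            else [
                [[int(x) for x in arr] for arr in per_locus]
                for per_locus in panel.allele_kmers
            ]
        ),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)
        fh.write("\n")


def load_panel_file(path: str) -> VariantPanel:
    with open(path) as fh:
        doc = json.load(fh)
    loci = [
        VariantLocus(
            chrom=l["chrom"],
            pos=l["pos"],
            ref_allele=l["ref"],
            alt_alleles=l["alts"],
            var_class=VarClass(l["class"]),
            source_ids=l.get("source_ids", []),
        )
        for l in doc["loci"]
    ]
    return VariantPanel(
        loci=loci,
        k=doc["k"],
        flank=doc["flank"],
        haplotypes=(
            None
            if doc["haplotypes"] is None
            else np.array(doc["haplotypes"], dtype=np.int8)
        ),
        haplotype_names=doc.get("haplotype_names"),
        allele_kmers=(
            None
            if doc["allele_kmers"] is None
            else [
                [np.array(arr, dtype=np.uint64) for arr in per_locus]
                for per_locus in doc["allele_kmers"]
            ]
        ),
        contig_lengths=doc.get("contig_lengths", {}),
    )
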