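"""Panel statistics (AF, HWE, LD) and strict genotype benchmarking.

The benchmark protocol assumes test and truth VCFs share the same
variant set and compares genotypes strictly, penalizing mismatched
zygosity: over-called alt dosage is a false positive (e.g. 1/1 against
a 0/1 truth), under-called dosage a false negative (0/1 against 1/1,
or a missing call where the truth carries the variant).  Counts are
stratified by variant class and repeat status, and precision / recall
/ F1 follow TP/(TP+FP), TP/(TP+FN) and their harmonic mean, with a
zero denominator reported as null rather than zero.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .errors import ValidationError
from .genotype import CohortGenotypes
from .panel import VariantLocus, VarClass

HWE_P_THRESHOLD = 1e-6  # loci with p <= this are flagged unreliable
DEFAULT_LD_WINDOW = 1_000_000  # bp
DEFAULT_LD_MIN_R2 = 0.8


# ---------------------------------------------------------------------------
# allele statistics


def allele_stats(cohort: CohortGenotypes) -> pd.DataFrame:
    """Per-locus AN, AC and AF over non-missing calls.

    AF columns hold one value per alternative allele; AF is None when
    every call is missing.
    """
    rows = []
    for l, locus in enumerate(cohort.panel.loci):
        gts = cohort.genotypes[l]
        present = gts[:, 0] >= 0
        an = int(2 * present.sum())
        counts = np.bincount(
            gts[present].ravel(), minlength=locus.n_alleles
        ) if an else np.zeros(locus.n_alleles, dtype=np.int64)
        ac = [int(c) for c in counts[1:]]
        af = [c / an for c in ac] if an else None
        rows.append(
            {
                "chrom": locus.chrom,
                "pos": locus.pos,
                "var_class": locus.var_class.value,
                "AN": an,
                "AC": ac,
                "AF": af,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test


def hwe_exact(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional Hardy-Weinberg test p-value.

    Sum of probabilities of all heterozygote counts that are as or less
    probable than the observed one, conditional on the allele counts
    (the standard exact HWE formulation).  A monomorphic locus has a
    single outcome and p = 1.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValidationError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValidationError("all-zero genotype counts")
    n_a = n_Aa + 2 * n_aa  # minor-ish allele count; symmetric anyway
    n_A = n_Aa + 2 * n_AA
    rare = min(n_A, n_a)
    if rare == 0:
        return 1.0
    # P(het = h | allele counts) up to a shared constant:
    # prob(h) ∝ n! / (nAA! nAa! naa!) * 2^h with nAa = h
    hets = np.arange(rare % 2, rare + 1, 2)
    from scipy.special import gammaln

    def logprob(h):
        aa = (rare - h) // 2
        AA = n - aa - h
        return (
            h * np.log(2.0)
            - gammaln(AA + 1)
            - gammaln(h + 1)
            - gammaln(aa + 1)
        )

    lp = logprob(hets.astype(np.float64))
    probs = np.exp(lp - lp.max())
    probs /= probs.sum()
    obs = probs[hets == n_Aa]
    if obs.size == 0:
        raise ValidationError(
            f"heterozygote count {n_Aa} impossible for allele counts"
        )
    return float(probs[probs <= obs[0] + 1e-12].sum())


def hwe_chisq(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Chi-square HWE test (1 df), for large cohorts."""
    from scipy.stats import chi2

    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValidationError("all-zero genotype counts")
    p = (2 * n_AA + n_Aa) / (2 * n)
    exp = np.array([n * p * p, 2 * n * p * (1 - p), n * (1 - p) ** 2])
    obs = np.array([n_AA, n_Aa, n_aa], dtype=float)
    if (exp == 0).any():
        return 1.0
    stat = ((obs - exp) ** 2 / exp).sum()
    return float(chi2.sf(stat, df=1))


# ---------------------------------------------------------------------------
# linkage disequilibrium


@dataclass
class LDPair:
    locus_a: int
    locus_b: int
    r2: float
    d_prime: float
    distance: int


def _biallelic_columns(haplotypes: np.ndarray) -> np.ndarray:
    """Collapse multi-allelic columns to major-allele-vs-rest (0/1)."""
    H = np.asarray(haplotypes)
    out = np.zeros_like(H, dtype=np.int8)
    for j in range(H.shape[1]):
        col = H[:, j]
        major = np.bincount(col).argmax()
        out[:, j] = (col != major).astype(np.int8)
    return out


def ld_pair(x: np.ndarray, y: np.ndarray) -> tuple[float, float] | None:
    """(r2, D') from two phased 0/1 haplotype columns; None if either
    is monomorphic."""
    pA, pB = x.mean(), y.mean()
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        return None
    pAB = (x * y).mean()
    D = pAB - pA * pB
    r2 = D * D / (pA * (1 - pA) * pB * (1 - pB))
    if D >= 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    d_prime = D / dmax if dmax > 0 else 0.0
    return float(r2), float(d_prime)


def ld_scan(
    panel_or_loci,
    haplotypes: np.ndarray | None = None,
    window_bp: int = DEFAULT_LD_WINDOW,
    r2_report: float = DEFAULT_LD_MIN_R2,
) -> list[LDPair]:
    """All locus pairs within a window with r^2 above the threshold.

    Accepts a phased ``VariantPanel`` (haplotypes taken from it) or a
    locus list plus a haplotype matrix.  Multi-allelic loci collapse to
    major-allele-vs-rest; pairs with a monomorphic member are skipped.
    Set ``r2_report=0`` to report every pair in the window.
    """
    if haplotypes is None:
        panel = panel_or_loci
        if not getattr(panel, "phased", False):
            raise ValidationError("ld_scan requires phased haplotypes")
        loci, H = panel.loci, panel.haplotypes
    else:
        loci, H = panel_or_loci, haplotypes
    B = _biallelic_columns(H)
    out: list[LDPair] = []
    for i in range(len(loci)):
        for j in range(i + 1, len(loci)):
            if loci[j].chrom != loci[i].chrom:
                break
            dist = loci[j].pos - loci[i].pos
            if dist > window_bp:
                break
            res = ld_pair(B[:, i].astype(float), B[:, j].astype(float))
            if res is None:
                continue
            r2, dp = res
            if r2 > r2_report:
                out.append(LDPair(i, j, r2, dp, int(dist)))
    return out


# ---------------------------------------------------------------------------
# strict benchmark protocol


@dataclass
class BenchCounts:
    per_stratum: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)

    def add(self, var_class: str, repeat: str, kind: str) -> None:
        key = (var_class, repeat)
        if key not in self.per_stratum:
            self.per_stratum[key] = np.zeros(3, dtype=np.int64)
        self.per_stratum[key][{"TP": 0, "FP": 1, "FN": 2}[kind]] += 1

    def totals(self) -> tuple[int, int, int]:
        agg = np.zeros(3, dtype=np.int64)
        for v in self.per_stratum.values():
            agg += v
        return int(agg[0]), int(agg[1]), int(agg[2])

    @property
    def TP(self) -> int:
        return self.totals()[0]

    @property
    def FP(self) -> int:
        return self.totals()[1]

    @property
    def FN(self) -> int:
        return self.totals()[2]


def _dosage(gt: tuple[int, int]) -> int:
    return sum(1 for a in gt if a > 0)


def compare_genotypes(
    called: tuple[int, int] | None, truth: tuple[int, int] | None
) -> str | None:
    """Strict single-call comparison; returns 'TP', 'FP', 'FN' or None.

    Exact genotype match on a variant-carrying call is a TP; an alt
    dosage called above the truth is an FP (1/1 against 0/1), below it
    an FN (0/1 against 1/1, or a missing call against a variant
    truth).  Any non-reference call against a 0/0 truth is an FP.
    Pairs where neither side carries the variant are not tallied.
    """
    if truth is None or truth[0] < 0:
        return None  # no usable truth
    t = tuple(sorted(truth))
    c = None if called is None or called[0] < 0 else tuple(sorted(called))
    td = _dosage(t)
    if c is None:
        return "FN" if td > 0 else None
    cd = _dosage(c)
    if c == t:
        return "TP" if td > 0 else None
    if cd > td:
        return "FP"
    if cd < td:
        return "FN"
    # equal dosage but different alleles (multi-allelic mismatch):
    # called an allele the truth does not carry
    return "FP"


def strict_compare(
    test_vcf: str,
    truth_vcf: str,
    loci: list[VariantLocus] | None = None,
    repeats: "IntervalTree | str | None" = None,
) -> BenchCounts:
    """Tally TP/FP/FN between a test and a truth VCF over the same
    variant set, stratified by variant class and repeat status.

    Both files must cover identical loci (the shared-site design);
    sample columns are matched by name when both files have the same
    names, else positionally.
    """
    from . import vcfio

    test_keys, test_samples, test_gts = vcfio.read_genotypes(test_vcf)
    truth_keys, truth_samples, truth_gts = vcfio.read_genotypes(truth_vcf)
    if test_keys != truth_keys:
        extra = [k for k in test_keys if k not in truth_keys][:5]
        missing = [k for k in truth_keys if k not in test_keys][:5]
        raise ValidationError(
            f"test/truth locus sets differ; test-only={extra}, "
            f"truth-only={missing}"
        )
    if set(test_samples) == set(truth_samples):
        order = [truth_samples.index(s) for s in test_samples]
        truth_gts = truth_gts[:, order]
    elif len(test_samples) != len(truth_samples):
        raise ValidationError("test/truth sample counts differ")

    if loci is not None:
        if len(loci) != len(test_keys):
            raise ValidationError("locus annotation length mismatch")
        classes = [l.var_class.value for l in loci]
        strata = stratify(loci, repeats) if repeats is not None else None
    else:
        classes = [
            classify_key(ref, alts).value for (_, _, ref, alts) in test_keys
        ]
        strata = None

    counts = BenchCounts()
    for i, key in enumerate(test_keys):
        repeat = strata[i][1] if strata is not None else "all"
        for s in range(test_gts.shape[1]):
            verdict = compare_genotypes(
                tuple(test_gts[i, s]), tuple(truth_gts[i, s])
            )
            if verdict:
                counts.add(classes[i], repeat, verdict)
    return counts


def classify_key(ref: str, alts: tuple[str, ...]) -> VarClass:
    from .panel import classify_variant

    return classify_variant(ref, list(alts)) if alts else VarClass.snp


def prf(counts: BenchCounts) -> pd.DataFrame:
    """Precision, recall and F1 per stratum plus an overall row.

    A metric whose denominator is zero is null (pd.NA), never 0.
    """

    def metrics(tp, fp, fn):
        p = tp / (tp + fp) if tp + fp else None
        r = tp / (tp + fn) if tp + fn else None
        f1 = (
            2 * p * r / (p + r)
            if p is not None and r is not None and (p + r) > 0
            else None
        )
        return p, r, f1

    rows = []
    for (vc, rep), (tp, fp, fn) in sorted(counts.per_stratum.items()):
        p, r, f1 = metrics(int(tp), int(fp), int(fn))
        rows.append(
            dict(var_class=vc, repeat=rep, TP=int(tp), FP=int(fp),
                 FN=int(fn), precision=p, recall=r, f1=f1)
        )
    tp, fp, fn = counts.totals()
    p, r, f1 = metrics(tp, fp, fn)
    rows.append(
        dict(var_class="all", repeat="all", TP=tp, FP=fp, FN=fn,
             precision=p, recall=r, f1=f1)
    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# repeat stratification


def load_repeats(bed_path: str) -> dict[str, IntervalTree]:
    """BED (0-based half-open) repeat intervals, one tree per chrom."""
    trees: dict[str, IntervalTree] = {}
    with open(os.fspath(bed_path)) as fh:
        for i, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(f"malformed BED line {i}: {line!r}")
            try:
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            except ValueError as e:
                raise ValidationError(f"malformed BED line {i}: {line!r}") from e
            if end > start:
                trees.setdefault(chrom, IntervalTree()).addi(start, end)
    return trees


def stratify(
    loci: list[VariantLocus],
    repeats: "IntervalTree | dict | str | None",
) -> list[tuple[str, str]]:
    """(variant class, repeat status) per locus.

    A locus is 'repeat' iff its half-open reference interval overlaps
    any repeat interval; a variant abutting an interval end is outside.
    """
    if isinstance(repeats, (str, os.PathLike)):
        trees = load_repeats(repeats)
    elif repeats is None:
        trees = {}
    elif isinstance(repeats, dict):
        trees = repeats
    else:
        trees = {"": repeats}
    out = []
    for locus in loci:
        tree = trees.get(locus.chrom, trees.get("")) if trees else None
        end = max(locus.end, locus.start + 1)  # insertions occupy a point
        hit = bool(tree is not None and tree.overlap(locus.start, end))
        out.append((locus.var_class.value, "repeat" if hit else "nonrepeat"))
    return out
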