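"""Emission model, k-mer-only genotyping, and the Li-Stephens HMM."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from popccdg import (
    EmissionParams,
    HMMParams,
    PopulationIndex,
    SampleMeta,
    VariantLocus,
    VariantPanel,
    emission_loglik,
    genotype_hmm,
    genotype_kmer_only,
    genotype_partition,
)
from popccdg.errors import ValidationError
from popccdg.genotype import (
    FLAG_IMPUTED,
    FLAG_UNINFORMATIVE,
    _calls_from_posteriors,
    _hmm_genotype_posteriors,
    genotype_pairs,
)
from popccdg.panel import VarClass

from oracles import brute_force_hmm_posteriors


def toy_panel(positions, hap_matrix=None, n_kmers=3, n_alleles=None, k=11):
    """Panel over synthetic loci with fabricated allele k-mer ids."""
    if n_alleles is None:
        n_alleles = [2] * len(positions)
    loci = [
        VariantLocus(
            chrom="chr1",
            pos=p,
            ref_allele="A",
            alt_alleles=["C" * (j + 1) for j in range(n_alleles[i] - 1)],
            var_class=VarClass.snp,
        )
        for i, p in enumerate(positions)
    ]
    allele_kmers = []
    next_id = 1
    for i in range(len(positions)):
        per_locus = []
        for a in range(n_alleles[i]):
            ids = np.arange(next_id, next_id + n_kmers[i][a] if isinstance(n_kmers, list) else next_id + n_kmers, dtype=np.uint64)
            next_id = int(ids[-1]) + 1 if ids.size else next_id
            per_locus.append(ids)
        allele_kmers.append(per_locus)
    return VariantPanel(
        loci=loci,
        k=k,
        flank=2 * (k - 1),
        haplotypes=None if hap_matrix is None else np.asarray(hap_matrix, dtype=np.int8),
        allele_kmers=allele_kmers,
    )


def toy_index(panel, counts_per_sample, depths, k=11):
    """Index whose rows are exactly the panel's fabricated k-mer ids.

    ``counts_per_sample[s][(l, a)]`` is the count of every k-mer of
    allele a at locus l in sample s.
    """
    all_ids = np.concatenate(
        [arr for per_locus in panel.allele_kmers for arr in per_locus]
    )
    keys = np.sort(all_ids)
    n = len(counts_per_sample)
    counts = np.zeros((keys.size, n), dtype=np.uint16)
    for s, spec in enumerate(counts_per_sample):
        for (l, a), c in spec.items():
            ids = panel.allele_kmers[l][a]
            idx = np.searchsorted(keys, ids)
            counts[idx, s] = c
    metas = [SampleMeta(f"s{i}", depth=d) for i, d in enumerate(depths)]
    return PopulationIndex(k=k, samples=metas, kmers=keys, counts=counts)


class TestEmissionLoglik:
    def test_poisson_term_example(self):
        # lambda=20, eps=0.01: het alt k-mer expects mu = 10.2
        params = EmissionParams(depth=20.0, error_rate=0.01)
        ll = emission_loglik(
            [np.array([]), np.array([10])], (1, 1), params
        )
        expected = 10 * math.log(10.2) - 10.2 - math.lgamma(11)
        assert ll == pytest.approx(expected, abs=1e-9)
        assert ll == pytest.approx(-2.081, abs=5e-3)

    def test_uninformative_zero(self):
        params = EmissionParams(depth=20.0)
        for cns in ((2, 0), (1, 1), (0, 2)):
            assert emission_loglik([np.array([]), np.array([])], cns, params) == 0.0

    def test_floor_prevents_minus_inf(self):
        params = EmissionParams(depth=20.0, error_rate=1e-12)
        ll = emission_loglik([np.array([]), np.array([50])], (2, 0), params)
        assert ll == params.floor_logprob

    def test_bad_copy_numbers_rejected(self):
        params = EmissionParams(depth=20.0)
        with pytest.raises(ValidationError):
            emission_loglik([np.array([1]), np.array([1])], (1, 2), params)

    def test_counts_capped(self):
        params = EmissionParams(depth=10.0)  # cap = 30
        a = emission_loglik([np.array([30])], (2,), params)
        b = emission_loglik([np.array([500])], (2,), params)
        assert a == b


class TestKmerOnlyGenotyping:
    def _two_sample_index(self, lam=20):
        panel = toy_panel([100], n_kmers=5)
        # sample 0: hom-alt (alt k-mers ~ lam, ref 0)
        # sample 1: hom-ref (ref k-mers ~ lam, alt 0)
        counts = [
            {(0, 1): lam},
            {(0, 0): lam},
        ]
        index = toy_index(panel, counts, [float(lam)] * 2)
        return panel, index

    def test_hom_alt_called(self):
        panel, index = self._two_sample_index()
        calls = genotype_kmer_only(panel, index, "s0")
        assert calls[0].genotype == (1, 1)
        assert calls[0].confidence > 0.99

    def test_hom_ref_called(self):
        panel, index = self._two_sample_index()
        calls = genotype_kmer_only(panel, index, "s1")
        assert calls[0].genotype == (0, 0)

    def test_het_called(self):
        panel = toy_panel([100], n_kmers=5)
        index = toy_index(panel, [{(0, 0): 10, (0, 1): 10}], [20.0])
        calls = genotype_kmer_only(panel, index, "s0")
        assert calls[0].genotype == (0, 1)

    def test_posteriors_normalized(self):
        panel, index = self._two_sample_index()
        for sid in ("s0", "s1"):
            for call in genotype_kmer_only(panel, index, sid):
                assert call.posteriors.sum() == pytest.approx(1.0, abs=1e-9)

    def test_uninformative_missing_call(self):
        panel = toy_panel([100], n_kmers=0)
        index = toy_index(panel, [{}], [20.0])
        # give the index at least one row
        index.kmers = np.array([999999], dtype=np.uint64)
        index.counts = np.zeros((1, 1), dtype=np.uint16)
        calls = genotype_kmer_only(panel, index, "s0")
        assert calls[0].genotype is None
        assert calls[0].confidence == 0.0
        assert calls[0].uninformative

    def test_unknown_sample_rejected(self):
        panel, index = self._two_sample_index()
        with pytest.raises(ValidationError):
            genotype_kmer_only(panel, index, "nope")

    def test_confidence_definition(self):
        post = np.array([[0.7], [0.2], [0.1]])
        _, conf = _calls_from_posteriors(post, genotype_pairs(2))
        assert conf[0] == pytest.approx(0.5)

    def test_monotone_in_alt_counts(self):
        """More alt k-mer evidence never lowers higher-alt genotypes."""
        panel = toy_panel([100], n_kmers=4)
        lam = 20.0
        prev = None
        for alt_count in range(0, 21, 2):
            index = toy_index(panel, [{(0, 0): 5, (0, 1): alt_count}], [lam])
            call = genotype_kmer_only(panel, index, "s0")[0]
            p = call.posteriors  # order: (0,0), (0,1), (1,1)
            if prev is not None:
                # cumulative mass of genotypes with alt copy >= 1 and >= 2
                assert p[1] + p[2] >= prev[1] + prev[2] - 1e-12
                assert p[2] >= prev[2] - 1e-12
            prev = p


class TestHMM:
    def test_identical_haplotypes_degenerate(self):
        panel = toy_panel([100, 200, 300], hap_matrix=[[1, 0, 1], [1, 0, 1]],
                          n_kmers=3)
        index = toy_index(
            panel, [{(0, 1): 20, (1, 0): 20, (2, 1): 20}], [20.0]
        )
        calls = genotype_hmm(panel, index, "s0")
        assert [c.genotype for c in calls] == [(1, 1), (0, 0), (1, 1)]
        for c in calls:
            assert c.posteriors.max() == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("case", range(6))
    def test_forward_backward_matches_enumeration(self, case):
        """Posterior equality with exhaustive path enumeration on all
        small panels (<= 4 loci, <= 3 haplotypes)."""
        rng = np.random.default_rng(1000 + case)
        L = int(rng.integers(2, 5))
        N = int(rng.integers(2, 4))
        n_alleles = [int(rng.integers(2, 4)) for _ in range(L)]
        haps = np.stack(
            [rng.integers(0, n_alleles[l], size=N) for l in range(L)], axis=1
        )
        positions = np.sort(rng.choice(np.arange(100, 100000), L, replace=False))
        panel = toy_panel(list(positions), hap_matrix=haps,
                          n_alleles=n_alleles, n_kmers=2)
        logliks = [
            rng.normal(-5, 3, size=len(genotype_pairs(n_alleles[l])))
            for l in range(L)
        ]
        hmm = HMMParams(rho=10 ** rng.uniform(-7, -4))
        got = _hmm_genotype_posteriors(panel, logliks, hmm)
        expected = brute_force_hmm_posteriors(
            haps,
            logliks,
            [genotype_pairs(n) for n in n_alleles],
            list(positions),
            hmm.rho,
        )
        for g, e in zip(got, expected):
            np.testing.assert_allclose(g, e, rtol=1e-9, atol=1e-12)

    def test_imputation_from_neighbors(self):
        """A k-mer-free middle locus takes its genotype from the
        haplotype carried by its confident neighbors."""
        haps = np.array([[1, 1, 1], [0, 0, 0]])
        panel = toy_panel([100, 200, 300], hap_matrix=haps,
                          n_kmers=[[3, 3], [0, 0], [3, 3]])
        index = toy_index(panel, [{(0, 1): 20, (2, 1): 20}], [20.0])
        calls = genotype_hmm(panel, index, "s0")
        assert calls[0].genotype == (1, 1)
        assert calls[1].genotype == (1, 1), "imputed through the haplotype"
        assert calls[1].imputed and calls[1].uninformative
        assert not calls[0].imputed

    def test_rho_zero_matches_no_transition_closed_form(self):
        """With rho=0 the chain is frozen: state posteriors are the
        normalized product of emissions over all loci."""
        rng = np.random.default_rng(7)
        haps = np.array([[0, 1, 1], [1, 0, 1], [0, 0, 0]])
        panel = toy_panel([100, 5000, 9000], hap_matrix=haps, n_kmers=2)
        logliks = [rng.normal(-4, 2, size=3) for _ in range(3)]
        got = _hmm_genotype_posteriors(panel, logliks, HMMParams(rho=0.0))
        N = 3
        pairs = genotype_pairs(2)
        weights = np.zeros((N, N))
        for i in range(N):
            for j in range(N):
                w = 0.0
                for l in range(3):
                    a = tuple(sorted((haps[i, l], haps[j, l])))
                    w += logliks[l][pairs.index(a)]
                weights[i, j] = math.exp(w)
        weights /= weights.sum()
        for l in range(3):
            expected = np.zeros(3)
            for i in range(N):
                for j in range(N):
                    a = tuple(sorted((haps[i, l], haps[j, l])))
                    expected[pairs.index(a)] += weights[i, j]
            np.testing.assert_allclose(got[l], expected, rtol=1e-9)

    def test_unphased_panel_rejected(self):
        panel = toy_panel([100], n_kmers=2)
        index = toy_index(panel, [{(0, 1): 10}], [20.0])
        with pytest.raises(ValidationError):
            genotype_hmm(panel, index, "s0")


class TestGenotypePartition:
    def _cohort(self, n=4, lam=20):
        rng = np.random.default_rng(3)
        panel = toy_panel([100, 900, 1700], n_kmers=4)
        counts = []
        for s in range(n):
            spec = {}
            for l in range(3):
                g = rng.integers(0, 3)
                if g >= 1:
                    spec[(l, 1)] = lam // 2 * g
                if g <= 1:
                    spec[(l, 0)] = lam // 2 * (2 - g)
            counts.append(spec)
        index = toy_index(panel, counts, [float(lam)] * n)
        return panel, index, counts

    def test_single_sample_matches_per_sample_op(self):
        panel, index, _ = self._cohort(n=1)
        cohort = genotype_partition(panel, index, mode="kmer")
        calls = genotype_kmer_only(panel, index, "s0")
        for l in range(3):
            assert tuple(cohort.genotypes[l, 0]) == calls[l].genotype
            assert cohort.confidence[l, 0] == pytest.approx(calls[l].confidence)

    def test_sample_order_invariance(self):
        panel, index, counts = self._cohort(n=4)
        cohort = genotype_partition(panel, index, mode="kmer")
        perm = [2, 0, 3, 1]
        index_p = toy_index(
            panel, [counts[i] for i in perm],
            [float(index.samples[i].depth) for i in perm],
        )
        for i, m in enumerate(index_p.samples):
            m.sample_id = f"s{perm[i]}"
        cohort_p = genotype_partition(panel, index_p, mode="kmer")
        for new, old in enumerate(perm):
            assert np.array_equal(
                cohort_p.genotypes[:, new], cohort.genotypes[:, old]
            )

    def test_split_equals_merged(self):
        panel, index, counts = self._cohort(n=4)
        whole = genotype_partition(panel, index, mode="kmer")
        left = toy_index(panel, counts[:2], [20.0, 20.0])
        right = toy_index(panel, counts[2:], [20.0, 20.0])
        for i, m in enumerate(right.samples):
            m.sample_id = f"s{i + 2}"
        part_l = genotype_partition(panel, left, mode="kmer")
        part_r = genotype_partition(panel, right, mode="kmer")
        merged = np.concatenate([part_l.genotypes, part_r.genotypes], axis=1)
        assert np.array_equal(merged, whole.genotypes)

    def test_uninformative_flagged_cohortwide(self):
        panel = toy_panel([100, 200], n_kmers=[[2, 2], [0, 0]])
        index = toy_index(panel, [{(0, 1): 20}], [20.0])
        cohort = genotype_partition(panel, index, mode="kmer")
        assert cohort.flags[1, 0] & FLAG_UNINFORMATIVE
        assert cohort.genotypes[1, 0, 0] == -1


@given(
    st.lists(
        st.floats(min_value=-30, max_value=0), min_size=3, max_size=3
    )
)
def test_posterior_normalization_property(lls):
    """Any emission log-likelihoods yield normalized posteriors."""
    panel = toy_panel([100], n_kmers=2)
    ll = np.array(lls)[:, None]
    w = np.exp(ll - ll.max())
    post = w / w.sum()
    assert post.sum() == pytest.approx(1.0, abs=1e-9)
    gts, conf = _calls_from_posteriors(post, genotype_pairs(2))
    assert 0.0 <= conf[0] <= 1.0
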