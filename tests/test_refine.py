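"""Median-confidence filter, imputation, phasing, and the 2-pass flow."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from popccdg import (
    RefinerConfig,
    aggregate_partitions,
    genotype_partition,
    impute_missing,
    median_confidence_filter,
    phase_cohort,
    two_pass,
)
from popccdg.errors import RefinerError, ValidationError
from popccdg.genotype import FLAG_FILTERED, FLAG_IMPUTED
from popccdg.refine import FLAG_LOWCONF_IMPUTED, subsample_haplotypes

from test_genotype import toy_index, toy_panel


def make_cohort(n_samples=5, n_loci=4, seed=0, lam=20):
    rng = np.random.default_rng(seed)
    panel = toy_panel(list(range(100, 100 + 500 * n_loci, 500)), n_kmers=4)
    counts = []
    for s in range(n_samples):
        spec = {}
        for l in range(n_loci):
            g = int(rng.integers(0, 3))
            if g >= 1:
                spec[(l, 1)] = int(rng.poisson(lam / 2 * g)) or 1
            if g <= 1:
                spec[(l, 0)] = int(rng.poisson(lam / 2 * (2 - g))) or 1
        counts.append(spec)
    index = toy_index(panel, counts, [float(lam)] * n_samples)
    return genotype_partition(panel, index, mode="kmer")


class TestAggregate:
    def test_single_partition_identity(self):
        c = make_cohort()
        out = aggregate_partitions([c])
        assert out.sample_ids == c.sample_ids
        assert np.array_equal(out.genotypes, c.genotypes)

    def test_concatenation(self):
        a, b = make_cohort(3, seed=1), make_cohort(2, seed=2)
        b.sample_ids = ["t0", "t1"]
        out = aggregate_partitions([a, b])
        assert out.n_samples == 5
        assert np.array_equal(out.genotypes[:, :3], a.genotypes)
        assert np.array_equal(out.genotypes[:, 3:], b.genotypes)

    def test_associative(self):
        parts = [make_cohort(2, seed=s) for s in range(3)]
        for i, p in enumerate(parts):
            p.sample_ids = [f"p{i}a", f"p{i}b"]
        left = aggregate_partitions([aggregate_partitions(parts[:2]), parts[2]])
        right = aggregate_partitions([parts[0], aggregate_partitions(parts[1:])])
        assert left.sample_ids == right.sample_ids
        assert np.array_equal(left.genotypes, right.genotypes)
        assert np.array_equal(left.confidence, right.confidence)

    def test_duplicate_samples_rejected(self):
        a, b = make_cohort(2, seed=1), make_cohort(2, seed=2)
        with pytest.raises(ValidationError):
            aggregate_partitions([a, b])


class TestMedianFilter:
    def test_printed_rule(self):
        c = make_cohort(5, n_loci=1)
        c.confidence[0] = [0.9, 0.8, 0.5, 0.4, 0.1]
        out, rep = median_confidence_filter(c)
        assert rep.thresholds[0] == 0.5
        assert rep.retained[0] == 3 and rep.filtered[0] == 2
        removed = out.genotypes[0, :, 0] < 0
        assert removed.tolist() == [False, False, False, True, True]
        assert all(out.flags[0, removed] & FLAG_FILTERED)

    def test_all_equal_nothing_removed(self):
        c = make_cohort(6, n_loci=2)
        c.confidence[:] = 0.7
        out, rep = median_confidence_filter(c)
        assert rep.filtered.sum() == 0
        assert np.array_equal(out.genotypes, c.genotypes)

    def test_thresholds_vary_by_locus(self):
        c = make_cohort(8, n_loci=3, seed=5)
        c.confidence[0] = np.linspace(0.1, 0.8, 8)
        c.confidence[1] = np.linspace(0.5, 0.99, 8)
        _, rep = median_confidence_filter(c)
        assert rep.thresholds[0] != rep.thresholds[1]

    def test_retained_calls_untouched(self):
        c = make_cohort(7, seed=3)
        out, _ = median_confidence_filter(c)
        kept = out.genotypes[:, :, 0] >= 0
        assert np.array_equal(out.genotypes[kept], c.genotypes[kept])

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=2, max_size=15))
    def test_never_removes_majority(self, confs):
        n = len(confs)
        c = make_cohort(n, n_loci=1, seed=9)
        c.confidence[0] = confs
        _, rep = median_confidence_filter(c)
        assert rep.retained[0] >= int(np.ceil(n / 2))


class TestImputeMissing:
    def test_prior_only_follows_cohort(self):
        """A k-mer-free missing call at an AF=1 locus is imputed 1/1."""
        c = make_cohort(5, n_loci=1)
        c.genotypes[0, :, :] = 1
        c.genotypes[0, 2] = (-1, -1)
        c.gt_logliks[0][:, 2] = 0.0  # no emission information
        out = impute_missing(c)
        assert tuple(out.genotypes[0, 2]) == (1, 1)
        assert out.flags[0, 2] & FLAG_IMPUTED

    def test_emission_dominates_prior(self):
        c = make_cohort(4, n_loci=1)
        c.genotypes[0, :2, :] = 0
        c.genotypes[0, 2:, :] = 1
        c.genotypes[0, 3] = (-1, -1)
        # strong hom-ref emissions for the missing sample
        c.gt_logliks[0][:, 3] = [-1.0, -40.0, -80.0]
        out = impute_missing(c)
        assert tuple(out.genotypes[0, 3]) == (0, 0)

    def test_no_retained_calls_uniform_fallback(self):
        c = make_cohort(3, n_loci=1)
        c.genotypes[0, :, :] = -1
        c.gt_logliks[0][:, :] = 0.0
        out = impute_missing(c)
        assert (out.genotypes[0, :, 0] >= 0).all()
        assert all(out.flags[0] & FLAG_LOWCONF_IMPUTED)

    def test_retained_calls_bit_identical(self):
        c = make_cohort(6, seed=4)
        filtered, _ = median_confidence_filter(c)
        out = impute_missing(filtered)
        kept = filtered.genotypes[:, :, 0] >= 0
        assert np.array_equal(out.genotypes[kept], filtered.genotypes[kept])
        assert not out.missing_mask().any()


class TestPhaseCohort:
    def test_all_homozygous_identity(self):
        c = make_cohort(4, n_loci=3, seed=6)
        c.genotypes[:, :, :] = 1
        c.genotypes[:, 2, :] = 0
        panel = phase_cohort(c, config=RefinerConfig(seed=1))
        assert c.haplotypes.shape == (8, 3)
        assert (c.haplotypes[:, 0] == c.genotypes[0, [0, 0, 1, 1, 2, 2, 3, 3], 0]).all()

    def test_deterministic_given_seed(self):
        for seed in (1, 99):
            runs = []
            for _ in range(2):
                c = make_cohort(6, n_loci=5, seed=8)
                phase_cohort(c, config=RefinerConfig(seed=seed))
                runs.append(c.haplotypes.copy())
            assert np.array_equal(runs[0], runs[1])

    def test_missing_genotypes_rejected(self):
        c = make_cohort(4, seed=2)
        c.genotypes[0, 0] = (-1, -1)
        with pytest.raises(ValidationError):
            phase_cohort(c)

    def test_switch_error_low_on_ld_cohort(self):
        """Cohort simulated from few founders with strong LD phases to
        a low switch-error rate against the true haplotypes."""
        from popccdg.simulate import (
            SimConfig,
            simulate_cohort,
            simulate_founders,
            simulate_reference,
        )
        from popccdg.genotype import CohortGenotypes
        from popccdg.panel import VariantLocus, VariantPanel, VarClass
        from popccdg.genotype import genotype_pairs

        cfg = SimConfig(
            ref_length=200_000,
            n_founders=6,
            n_snp=120,
            n_small_indel=0,
            n_sv_indel=0,
            n_samples=20,
            recomb_rate=1e-5,
            seed=31,
        )
        ref = simulate_reference(cfg)
        founders = simulate_founders(ref, cfg)
        truth = simulate_cohort(founders, cfg)
        loci = [
            VariantLocus("chrSim", v.pos, v.ref, [v.alt], VarClass.snp)
            for v in founders.variants
        ]
        panel = VariantPanel(loci=loci, k=31, flank=60)
        n_loci, n = truth.n_variants, cfg.n_samples
        # perfect genotypes, phase to be recovered
        cohort = CohortGenotypes(
            panel=panel,
            sample_ids=truth.sample_ids,
            genotypes=np.sort(truth.genotypes, axis=2).astype(np.int8),
            confidence=np.ones((n_loci, n)),
            flags=np.zeros((n_loci, n), dtype=np.uint8),
            gt_logliks=[np.zeros((3, n)) for _ in range(n_loci)],
            depths=np.full(n, 20.0),
            partition_ids=np.zeros(n, dtype=int),
        )
        phase_cohort(cohort, panel, RefinerConfig(seed=5))
        switches = 0
        opportunities = 0
        for s in range(n):
            t1 = truth.genotypes[:, s, 0]
            t2 = truth.genotypes[:, s, 1]
            p1 = cohort.haplotypes[2 * s]
            het = t1 != t2
            idx = np.flatnonzero(het)
            if idx.size < 2:
                continue
            # orientation of each phased het relative to truth
            orient = p1[idx] == t1[idx]
            switches += int((orient[1:] != orient[:-1]).sum())
            opportunities += idx.size - 1
        rate = switches / opportunities
        assert rate <= 0.05, f"switch error {rate:.3f}"


class TestSubsampleHaplotypes:
    def test_small_input_passthrough(self):
        H = np.eye(4, dtype=np.int8)
        assert np.array_equal(subsample_haplotypes(H, 8), H)

    def test_greedy_diversity_deterministic(self):
        rng = np.random.default_rng(0)
        H = rng.integers(0, 2, size=(40, 30)).astype(np.int8)
        a = subsample_haplotypes(H, 8)
        b = subsample_haplotypes(H, 8)
        assert np.array_equal(a, b)
        assert a.shape == (8, 30)
        # chosen set is diverse: no duplicate rows when distinct exist
        assert len({tuple(r) for r in a}) == 8


class TestTwoPass:
    def _panel_and_indexes(self):
        rng = np.random.default_rng(12)
        panel = toy_panel([100, 600, 1100, 1600], n_kmers=4)
        lam = 20
        counts = []
        gts = rng.integers(0, 3, size=(4, 6))
        for s in range(6):
            spec = {}
            for l in range(4):
                g = gts[l, s]
                if g >= 1:
                    spec[(l, 1)] = int(rng.poisson(lam / 2 * g)) or 1
                if g <= 1:
                    spec[(l, 0)] = int(rng.poisson(lam / 2 * (2 - g))) or 1
            counts.append(spec)
        left = toy_index(panel, counts[:3], [float(lam)] * 3)
        right = toy_index(panel, counts[3:], [float(lam)] * 3)
        for i, m in enumerate(right.samples):
            m.sample_id = f"s{i + 3}"
        return panel, [left, right]

    def test_stage_log_has_two_passes(self):
        panel, indexes = self._panel_and_indexes()
        log = []
        cohort = two_pass(panel, indexes, RefinerConfig(seed=3), log=log)
        stages = [e["stage"] for e in log]
        assert stages.count("genotype_pass1") == 1
        assert stages.count("genotype_pass2") == 1
        assert sum(s.startswith("filter_") for s in stages) == 2
        assert cohort.n_samples == 6
        assert cohort.haplotypes is not None
        assert not cohort.missing_mask().any()

    def test_phased_input_skips_pass1(self):
        panel, indexes = self._panel_and_indexes()
        phased = panel.with_haplotypes(
            np.array([[0, 0, 1, 1], [1, 0, 0, 1]], dtype=np.int8)
        )
        log = []
        two_pass(phased, indexes, RefinerConfig(seed=3), log=log)
        stages = [e["stage"] for e in log]
        assert stages[0] == "pass1_skipped"
        assert "genotype_pass1" not in stages

    def test_deterministic(self):
        panel, indexes = self._panel_and_indexes()
        a = two_pass(panel, indexes, RefinerConfig(seed=4))
        b = two_pass(panel, indexes, RefinerConfig(seed=4))
        assert np.array_equal(a.genotypes, b.genotypes)
        assert np.array_equal(a.haplotypes, b.haplotypes)


class TestExternalRefinerHook:
    def test_failing_command_raises(self):
        c = make_cohort(3, seed=1)
        c.panel.contig_lengths = {"chr1": 100000}
        cfg = RefinerConfig(
            backend="external_command",
            command_template="false {in_vcf} {out_vcf}",
        )
        with pytest.raises(RefinerError):
            impute_missing(c, config=cfg)

    def test_round_trip_via_copy_command(self):
        c = make_cohort(3, seed=1)
        c.panel.contig_lengths = {"chr1": 100000}
        cfg = RefinerConfig(
            backend="external_command",
            command_template="cp {in_vcf} {out_vcf}",
        )
        out = impute_missing(c, config=cfg)
        assert np.array_equal(
            np.sort(out.genotypes, axis=2), np.sort(c.genotypes, axis=2)
        )


class TestConfidenceSpill:
    def test_round_trip_matches_cohort(self, tmp_path):
        from popccdg.refine import read_confidence_table, write_confidence_table

        c = make_cohort(4, n_loci=3, seed=21)
        c.genotypes[1, 2] = (-1, -1)
        path = tmp_path / "part0.conf.tsv"
        write_confidence_table(c, str(path))
        df = read_confidence_table(str(path))
        assert len(df) == c.n_loci * c.n_samples
        assert set(df.columns) == {"chrom", "pos", "sample", "call", "confidence"}
        row = df[(df["pos"] == c.panel.loci[1].pos) & (df["sample"] == "s2")]
        assert row.iloc[0]["call"] == "./."
        got = df[(df["pos"] == c.panel.loci[0].pos) & (df["sample"] == "s0")]
        assert got.iloc[0]["confidence"] == pytest.approx(
            float(c.confidence[0, 0]), abs=1e-6
        )
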