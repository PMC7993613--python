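import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bsakit import poolscan, simcross
from bsakit.simcross import (
    CrossDesign,
    F2Cohort,
    InvalidDesignError,
    InvalidMixtureError,
)


class TestCrossDesign:
    def test_defaults_valid(self):
        d = simcross.paper_design()
        assert d.morgans == pytest.approx(d.chrom_length_bp * d.recomb_rate)

    @pytest.mark.parametrize(
        "kw",
        [
            {"n_snps": 0},
            {"n_f2": 0},
            {"chrom_length_bp": 0},
            {"pool_sizes": (30, 30)},  # sums beyond n_f2
            {"pool_sizes": (0, 40)},
            {"misphenotype_prob": 1.5},
            {"base_error": -0.1},
            {"coverage": (0.0, 30.0)},
            {"causal_pos": 99_999_999_999},
        ],
    )
    def test_invalid_designs_rejected(self, kw):
        with pytest.raises(InvalidDesignError):
            CrossDesign(**kw)


class TestFounders:
    def test_fixed_difference_construction(self):
        d = CrossDesign(n_snps=10, chrom_length_bp=1_000, causal_pos=500)
        f = simcross.simulate_founders(d)
        # mutant founder is alt everywhere by construction: allele 1 marks it
        assert f.n_snps == 10
        assert np.all(np.diff(f.positions) > 0)

    def test_causal_maps_to_nearest_snp(self):
        d = CrossDesign(n_snps=50, chrom_length_bp=100_000, causal_pos=50_000)
        f = simcross.simulate_founders(d)
        dists = np.abs(f.positions - d.causal_pos)
        assert dists[f.causal_index] == dists.min()

    def test_same_seed_identical(self):
        d = CrossDesign(seed=7)
        f1 = simcross.simulate_founders(d)
        f2 = simcross.simulate_founders(d)
        np.testing.assert_array_equal(f1.positions, f2.positions)
        assert f1.causal_index == f2.causal_index


class TestF2Cross:
    def test_mendelian_segregation_10000(self):
        # causal genotype counts over 10,000 F2 are ~1:2:1
        d = CrossDesign(n_f2=10_000, n_snps=5, chrom_length_bp=10_000, causal_pos=5_000, seed=11)
        f = simcross.simulate_founders(d)
        c = simcross.simulate_f2_cross(f, d)
        counts = np.bincount(c.causal_genotype, minlength=3)
        res = stats.chisquare(counts, f_exp=np.array([0.25, 0.5, 0.25]) * d.n_f2)
        assert res.pvalue > 0.01

    def test_haldane_recombinant_fraction(self):
        # gamete-level recombinant fraction between two SNPs matches the
        # Haldane map function r = (1 - exp(-2d)) / 2
        d = CrossDesign(n_snps=2, chrom_length_bp=1_000_000, recomb_rate=1e-8,
                        causal_pos=500_000, seed=5)
        f = simcross.simulate_founders(d)
        rng = np.random.default_rng(42)
        n = 200_000
        g = simcross.simulate_gametes(n, f, d, rng)
        d_morgans = (f.positions[1] - f.positions[0]) * d.recomb_rate
        expected = (1.0 - np.exp(-2.0 * d_morgans)) / 2.0
        observed = float(np.mean(g[:, 0] != g[:, 1]))
        sd = np.sqrt(expected * (1 - expected) / n)
        assert abs(observed - expected) < 4 * sd

    def test_haldane_worked_value(self):
        # the map function itself at d = 0.01 Morgans
        assert (1 - np.exp(-0.02)) / 2 == pytest.approx(0.0099, abs=1e-4)

    def test_phenotype_equals_recessive_rule_without_misphenotyping(self):
        d = CrossDesign(n_f2=500, n_snps=10, chrom_length_bp=100_000,
                        causal_pos=50_000, misphenotype_prob=0.0, pool_sizes=(12, 40))
        f = simcross.simulate_founders(d)
        c = simcross.simulate_f2_cross(f, d)
        np.testing.assert_array_equal(c.labeled_mutant, c.causal_genotype == 2)

    def test_misphenotyping_only_mislabels_homozygous_mutants(self):
        d = CrossDesign(n_f2=2_000, n_snps=10, chrom_length_bp=100_000,
                        causal_pos=50_000, misphenotype_prob=0.5, seed=2)
        f = simcross.simulate_founders(d)
        c = simcross.simulate_f2_cross(f, d)
        # labelled mutant implies truly homozygous; some homozygotes are hidden
        assert np.all(c.causal_genotype[c.labeled_mutant] == 2)
        n_hom = int((c.causal_genotype == 2).sum())
        assert 0 < int(c.labeled_mutant.sum()) < n_hom

    def test_alleles_trace_to_founder_haplotypes(self):
        d = CrossDesign(n_f2=20, pool_sizes=(5, 10), n_snps=50,
                        chrom_length_bp=100_000, causal_pos=1)
        f = simcross.simulate_founders(d)
        c = simcross.simulate_f2_cross(f, d)
        for g in c.gametes:
            assert set(np.unique(g)) <= {0, 1}
        np.testing.assert_array_equal(c.genotypes, c.gametes[0] + c.gametes[1])

    def test_ibd_around_causal_locus(self, small_sim):
        # with misphenotype_prob = 0, every mutant-pool animal is homozygous
        # for the mutant founder haplotype across a tightly linked region
        design, founders, cohort, _ = small_sim
        assert design.misphenotype_prob == 0.0
        lo, hi = founders.causal_index - 50, founders.causal_index + 51
        mut = cohort.labeled_mutant
        for g in cohort.gametes:
            assert np.all(g[mut, lo:hi] == 1)

    def test_determinism(self):
        d = CrossDesign(seed=9, n_snps=100, chrom_length_bp=1_000_000, causal_pos=1)
        f = simcross.simulate_founders(d)
        c1 = simcross.simulate_f2_cross(f, d)
        c2 = simcross.simulate_f2_cross(f, d)
        np.testing.assert_array_equal(c1.genotypes, c2.genotypes)
        np.testing.assert_array_equal(c1.labeled_mutant, c2.labeled_mutant)


class TestPoolAndSequence:
    def _fixed_cohort(self, founders, dosage):
        n, m = 60, founders.n_snps
        g1 = np.full((n, m), dosage // 2, dtype=np.uint8)
        g2 = np.full((n, m), dosage - dosage // 2, dtype=np.uint8)
        genotypes = (g1 + g2).astype(np.int8)
        labeled = np.zeros(n, dtype=bool)
        labeled[:15] = True  # phenotype split independent of dosage here
        return F2Cohort((g1, g2), genotypes, labeled, genotypes[:, 0].copy())

    def test_monomorphic_ref_gives_zero_alt_without_error(self):
        d = CrossDesign(n_f2=60, pool_sizes=(12, 40), n_snps=200,
                        chrom_length_bp=1_000_000, causal_pos=1, base_error=0.0)
        f = simcross.simulate_founders(d)
        sites = simcross.pool_and_sequence(self._fixed_cohort(f, 0), d, f)
        assert (sites["mut_alt"] == 0).all()
        assert (sites["wt_alt"] == 0).all()

    def test_depth_mean_within_one_percent(self):
        d = CrossDesign(n_f2=60, pool_sizes=(12, 40), n_snps=10_000,
                        chrom_length_bp=50_000_000, causal_pos=1, seed=4)
        f = simcross.simulate_founders(d)
        sites = simcross.pool_and_sequence(self._fixed_cohort(f, 1), d, f)
        for pool, cov in zip(("mut", "wt"), d.coverage):
            depth = (sites[f"{pool}_ref"] + sites[f"{pool}_alt"]).mean()
            assert abs(depth - cov) / cov < 0.01

    def test_alt_frequency_unbiased(self):
        # all-het cohort: true pool frequency is exactly 1/2 at every site
        d = CrossDesign(n_f2=60, pool_sizes=(12, 40), n_snps=10_000,
                        chrom_length_bp=50_000_000, causal_pos=1, seed=8)
        f = simcross.simulate_founders(d)
        sites = simcross.pool_and_sequence(self._fixed_cohort(f, 1), d, f)
        for pool in ("mut", "wt"):
            freq = sites[f"{pool}_alt"] / (sites[f"{pool}_ref"] + sites[f"{pool}_alt"])
            assert abs(freq.mean() - 0.5) < 0.005

    def test_empty_pool_raises(self):
        d = CrossDesign(n_f2=60, pool_sizes=(12, 40), n_snps=10,
                        chrom_length_bp=1_000, causal_pos=1)
        f = simcross.simulate_founders(d)
        c = self._fixed_cohort(f, 1)
        all_wild = F2Cohort(c.gametes, c.genotypes, np.zeros(60, bool), c.causal_genotype)
        with pytest.raises(InvalidDesignError):
            simcross.pool_and_sequence(all_wild, d, f)

    def test_determinism(self, small_sim):
        design, founders, cohort, sites = small_sim
        again = simcross.pool_and_sequence(cohort, design, founders)
        pd.testing.assert_frame_equal(sites, again)


class TestUnlinkedSites:
    def test_null_daf_matches_closed_form(self):
        sites = simcross.simulate_unlinked_sites(50_000, seed=1)
        daf, n_excluded = poolscan.delta_af_table(sites)
        expected = simcross.expected_null_delta_af()
        assert abs(np.nanmean(daf) - expected) < 0.015
        assert n_excluded < 10

    def test_invalid_count(self):
        with pytest.raises(InvalidDesignError):
            simcross.simulate_unlinked_sites(0)


class TestReferencePanel:
    def test_causal_site_has_zero_alt(self, small_sim):
        _, founders, _, _ = small_sim
        panel = simcross.simulate_reference_panel(founders, n_samples=20, seed=3)
        sample_cols = [c for c in panel.columns if c.startswith("sample_")]
        assert len(sample_cols) == 20  # mirrors the 14 + 6 sample panel
        causal_row = panel[panel["pos"] == founders.causal_pos]
        assert (causal_row[sample_cols].to_numpy() == 0).all()
        # other sites are polymorphic somewhere
        assert panel[sample_cols].to_numpy().sum() > 0

    def test_determinism(self, small_sim):
        _, founders, _, _ = small_sim
        p1 = simcross.simulate_reference_panel(founders, 5, seed=9)
        p2 = simcross.simulate_reference_panel(founders, 5, seed=9)
        pd.testing.assert_frame_equal(p1, p2)

    def test_invalid_sample_count(self, small_sim):
        _, founders, _, _ = small_sim
        with pytest.raises(InvalidDesignError):
            simcross.simulate_reference_panel(founders, 0)


class TestAmpliconReads:
    TEMPLATES = [("iso_a", "ACGTACGTACGTACGTACGT"), ("iso_b", "TTTTCCCCGGGGAAAATTTT")]

    def test_error_free_reads_equal_template_with_prefix(self):
        reads = simcross.simulate_amplicon_reads(
            [self.TEMPLATES[0]], [1.0], "AAAAAAA", "CCCCCCCCCC", 20, 0.0, seed=0
        )
        for r in reads:
            assert r.sequence == "AAAAAAA" + "CCCCCCCCCC" + self.TEMPLATES[0][1]
            assert r.true_isoform == "iso_a"

    def test_all_reads_start_with_barcode(self):
        reads = simcross.simulate_amplicon_reads(
            self.TEMPLATES, [0.5, 0.5], "ACGTACG", "TTTTTTTTTT", 50, 0.3, seed=1
        )
        # substitutions may hit the prefix, so check the clean-prefix majority
        clean = sum(r.sequence.startswith("ACGTACG") for r in reads)
        assert clean > 0
        reads0 = simcross.simulate_amplicon_reads(
            self.TEMPLATES, [0.5, 0.5], "ACGTACG", "TTTTTTTTTT", 50, 0.0, seed=1
        )
        assert all(r.sequence.startswith("ACGTACG" + "TTTTTTTTTT") for r in reads0)

    def test_mixture_counts_within_3_sd(self):
        mix = [0.4, 0.5, 0.1]
        templates = self.TEMPLATES + [("iso_c", "GGGGGGGGGGGGGGGGGGGG")]
        reads = simcross.simulate_amplicon_reads(
            templates, mix, "ACGTACG", "TTTTTTTTTT", 1_000, 0.0, seed=2
        )
        counts = pd.Series([r.true_isoform for r in reads]).value_counts()
        for (iso, _), p in zip(templates, mix):
            expected = 1_000 * p
            sd = np.sqrt(1_000 * p * (1 - p))
            assert abs(counts.get(iso, 0) - expected) <= 3 * sd

    @pytest.mark.parametrize(
        "kw",
        [
            {"mixture": [0.5, 0.6]},  # does not sum to 1
            {"mixture": [1.0]},  # length mismatch
            {"mixture": [-0.5, 1.5]},  # negative proportion
            {"barcode": "ACGT"},  # not 7 bp
        ],
    )
    def test_malformed_inputs_raise(self, kw):
        args = dict(
            isoforms=self.TEMPLATES, mixture=[0.5, 0.5], barcode="ACGTACG",
            adapter="TTTTTTTTTT", n_reads=5, error_rate=0.0, seed=0,
        )
        args.update(kw)
        with pytest.raises(InvalidMixtureError):
            simcross.simulate_amplicon_reads(**args)

    def test_determinism(self):
        kw = dict(mixture=[0.5, 0.5], barcode="ACGTACG", adapter="TTTTTTTTTT",
                  n_reads=30, error_rate=0.2, seed=6)
        r1 = simcross.simulate_amplicon_reads(self.TEMPLATES, **kw)
        r2 = simcross.simulate_amplicon_reads(self.TEMPLATES, **kw)
        assert [x.sequence for x in r1] == [x.sequence for x in r2]


class TestBsaDataset:
    def test_combined_table_sorted_and_deterministic(self):
        d = simcross.mapping_design(seed=1, n_snps=500)
        data1 = simcross.simulate_bsa_dataset(d, background_sites=1_000)
        data2 = simcross.simulate_bsa_dataset(d, background_sites=1_000)
        pd.testing.assert_frame_equal(data1["sites"], data2["sites"])
        sites = data1["sites"]
        for _, grp in sites.groupby("chrom"):
            assert grp["pos"].is_monotonic_increasing
        # panel covers every site and lacks the causal allele
        assert len(data1["panel"]) == len(sites)

    def test_annotate_consequences_marks_causal(self):
        d = simcross.mapping_design(seed=2, n_snps=500)
        data = simcross.simulate_bsa_dataset(d, background_sites=500)
        ann = simcross.annotate_consequences(
            data["sites"], data["causal_chrom"], data["causal_pos"], seed=2
        )
        causal = ann[(ann["chrom"] == data["causal_chrom"]) & (ann["pos"] == data["causal_pos"])]
        assert causal["consequence"].tolist() == ["splice_donor_variant"]
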