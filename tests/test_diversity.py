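"""Diversity summaries, LD statistics, Ne estimation and replicate QC."""

import numpy as np
import pandas as pd
import pytest

from conftest import genotype_matrix_from_codes
from foxgbs import diversity, simulate as sim
from foxgbs.core import MISSING


class TestPopulationSummary:
    def test_expected_het_small_sample_formula(self):
        # N = 10, p = 0.5: (2N / (2N-1)) * 2pq = (20/19) * 0.5
        val = diversity.expected_het_unbiased(np.array([0.5]), np.array([10]))
        assert val[0] == pytest.approx(20 / 19 * 0.5)

    def test_expected_het_large_n_limit(self):
        val = diversity.expected_het_unbiased(np.array([0.5]), np.array([10_000]))
        assert val[0] == pytest.approx(0.5, abs=1e-4)

    def test_fixed_snp_counted_with_zeroes(self):
        gm = genotype_matrix_from_codes([[0, 0, 0], [0, 1, 1]])
        out = diversity.population_summary(gm, gm.samples)
        assert out["n_fixed"] == 1
        assert out["n_snps"] == 2
        assert out["mean_maf"] == pytest.approx((0.0 + 1 / 3) / 2)

    def test_empty_population_rejected(self):
        gm = genotype_matrix_from_codes([[0, 1]])
        with pytest.raises(ValueError):
            diversity.population_summary(gm, [])

    def test_hexp_exceeds_hobs_under_het_undercalling(self, called_cohort, populations):
        gm, _ = called_cohort
        for pop in populations:
            out = diversity.population_summary(gm, pop)
            assert out["mean_expected_het"] >= out["mean_observed_het"]
            assert 0 <= out["mean_maf"] <= 0.53


class TestLdR2:
    def test_identical_and_mirrored_columns(self):
        a = np.array([0, 1, 2, 1, 0], dtype=float)
        assert diversity.ld_r2(a, a) == pytest.approx(1.0)
        assert diversity.ld_r2(a, 2 - a) == pytest.approx(1.0)

    def test_monomorphic_subset_undefined(self):
        a = np.array([1.0, 1.0, 1.0])
        b = np.array([0.0, 1.0, 2.0])
        assert np.isnan(diversity.ld_r2(a, b))

    def test_null_mean_near_one_over_n(self):
        rng = np.random.default_rng(2)
        n_samples, n_pairs = 20, 4000
        vals = []
        for _ in range(n_pairs):
            a = rng.binomial(2, 0.5, n_samples).astype(float)
            b = rng.binomial(2, 0.5, n_samples).astype(float)
            v = diversity.ld_r2(a, b)
            if not np.isnan(v):
                vals.append(v)
        # E[r^2] ~ 1/n for independent loci; SE of the mean ~ sqrt(2)/n/sqrt(m)
        mean = np.mean(vals)
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(mean - 1 / n_samples) < 3 * se


class TestLdDecay:
    def _block_matrix(self):
        # 3 tight blocks of 4 identical SNPs each, blocks far apart and
        # independent: r^2 = 1 within blocks, low between them
        rng = np.random.default_rng(3)
        rows, pos = [], []
        for b in range(3):
            col = rng.binomial(2, 0.5, 30)
            for k in range(4):
                rows.append(col)
                pos.append(b * 20_000_000 + k * 200 + 1)
        return genotype_matrix_from_codes(np.array(rows), pos=pos)

    def test_first_bin_assignment_and_conservation(self):
        gm = self._block_matrix()
        bins = diversity.ld_decay_bins(gm)
        assert len(bins) == 14
        n_total = sum(b.n_pairs for b in bins)
        assert n_total == 12 * 11 // 2  # all intra-chromosome pairs
        assert bins[0].n_pairs == 3 * (4 * 3 // 2)  # within-block pairs < 1 kb
        assert bins[0].mean_r2 == pytest.approx(1.0)
        assert bins[0].frac_r2_one == pytest.approx(1.0)

    def test_decay_monotone_on_block_structure(self):
        gm = self._block_matrix()
        bins = diversity.ld_decay_bins(gm)
        means = [b.mean_r2 for b in bins if not np.isnan(b.mean_r2)]
        assert means[0] >= means[-1]
        assert means[0] == pytest.approx(1.0)


class TestInterchromosomeNull:
    def test_null_mean_and_determinism(self):
        rng = np.random.default_rng(4)
        n_samples = 20
        gt = rng.binomial(2, 0.5, size=(60, n_samples)).astype(np.int8)
        chrom = np.repeat(["1", "2", "3"], 20)
        gm = genotype_matrix_from_codes(gt, chrom=chrom)
        m1, sd1, n1 = diversity.interchromosome_ld_null(gm, seed=7)
        m2, _, _ = diversity.interchromosome_ld_null(gm, seed=7)
        assert m1 == m2
        assert n1 == 3 * 20 * 20
        assert abs(m1 - 1 / n_samples) < 3 * sd1 / np.sqrt(n1)

    def test_duplicated_chromosome_detected(self):
        rng = np.random.default_rng(5)
        col = rng.binomial(2, 0.5, size=(10, 25)).astype(np.int8)
        gt = np.vstack([col, col])  # chromosome 2 duplicates chromosome 1
        chrom = np.repeat(["1", "2"], 10)
        gm = genotype_matrix_from_codes(gt, chrom=chrom)
        r2 = diversity._cross_chrom_r2(gm)
        assert np.isclose(r2, 1.0).sum() >= 10

    def test_single_chromosome_rejected(self):
        gm = genotype_matrix_from_codes([[0, 1, 2], [1, 1, 0]])
        with pytest.raises(ValueError):
            diversity.interchromosome_ld_null(gm)


class TestNeEstimate:
    def test_pure_sampling_noise_gives_infinite(self):
        # corrected r^2 <= 0 must flag an unbounded estimate
        ne = diversity._ne_from_r2prime(np.array([0.0, -0.01]), 40)
        assert np.isinf(ne).all()

    def test_monotone_in_sample_size(self):
        r2 = 0.03
        ne_small = diversity._ne_from_r2prime(
            np.array([r2 - diversity._sampling_expectation(30)]), 30
        )[0]
        ne_large = diversity._ne_from_r2prime(
            np.array([r2 - diversity._sampling_expectation(50)]), 50
        )[0]
        assert ne_large < ne_small

    def test_wright_fisher_recovery_within_factor_two(self):
        nes = []
        for seed in (1, 2, 3):
            gmx = sim.wright_fisher_cohort(ne=50, generations=5, n_loci=400, seed=seed)
            est = diversity.estimate_ne_ld(gmx, maf_cutoff=0.05, max_pairs=60_000, seed=seed)
            assert est.ci_low <= est.ne <= est.ci_high
            nes.append(est.ne)
        med = np.median(nes)
        assert 25 <= med <= 100


class TestConcordance:
    def test_identical_replicates_fully_concordant(self):
        gm = genotype_matrix_from_codes(
            [[0, 0], [1, 1], [2, 2]], samples=["a", "a_r"]
        )
        table, summary = diversity.concordance_report(gm, [("a", "a_r")])
        assert table.pct_concordant[0] == 100.0

    def test_all_missing_replicate_is_discordant_missing(self):
        gm = genotype_matrix_from_codes(
            [[0, MISSING], [1, MISSING]], samples=["a", "a_r"]
        )
        table, _ = diversity.concordance_report(gm, [("a", "a_r")])
        assert table.pct_discordant_missing[0] == 100.0

    def test_depth_ratio_one_decimal(self):
        assert diversity.depth_ratio(34.0, 14.0) == 2.4

    def test_unpaired_replicate_rejected(self):
        gm = genotype_matrix_from_codes([[0, 0]], samples=["a", "b"])
        with pytest.raises(KeyError):
            diversity.concordance_report(gm, [("a", "zz")])

    def test_stringent_beats_filtered_concordance(self, called_cohort, small_cohort):
        from foxgbs import filtering

        gm, truth = called_cohort
        pairs = truth.manifest.replicate_pairs()
        filt, _ = filtering.apply_filtered(gm)
        strict = filtering.apply_stringent(filt)
        t_f, _ = diversity.concordance_report(filt, pairs)
        t_s, _ = diversity.concordance_report(strict, pairs)
        assert t_s.pct_concordant.mean() > t_f.pct_concordant.mean()

    def test_discordant_sites_shallower_than_concordant(self, called_cohort, small_cohort):
        from foxgbs import filtering

        gm, truth = called_cohort
        filt, _ = filtering.apply_filtered(gm)
        _, summary = diversity.concordance_report(
            filt, truth.manifest.replicate_pairs()
        )
        assert summary["mean_depth_concordant"] > summary["mean_depth_discordant"]


class TestXHetBySex:
    def test_clean_haploid_males_show_zero_het(self):
        gt = np.array([[2, 1], [0, 1], [2, 2]], dtype=np.int8)
        gm = genotype_matrix_from_codes(
            gt, chrom=["X"] * 3, pos=[7e6, 8e6, 9e6], samples=["m1", "f1"]
        )
        out = diversity.x_het_by_sex(gm, {"m1": "M", "f1": "F"})
        male = out[out.sex == "M"].iloc[0]
        female = out[out.sex == "F"].iloc[0]
        assert male.mean_het == 0.0
        assert female.mean_het == pytest.approx(2 / 3)

    def test_par_snps_excluded(self):
        gt = np.array([[1, 1], [1, 1]], dtype=np.int8)
        gm = genotype_matrix_from_codes(
            gt, chrom=["X", "X"], pos=[6_000_000, 8_000_000], samples=["m1", "f1"]
        )
        out = diversity.x_het_by_sex(gm, {"m1": "M", "f1": "F"})
        assert (out.n_snps == 1).all()  # only the non-PAR SNP counts

    def test_low_depth_inflates_male_x_het(self, called_cohort, small_cohort):
        gm, truth = called_cohort
        sexes = truth.manifest.sex_of()
        out = diversity.x_het_by_sex(gm, sexes, par_end=truth.par_end)
        male = out[out.sex == "M"].iloc[0]
        # truth has zero male non-PAR heterozygosity; called data shows > 0
        assert male.n_snps > 0
        assert male.mean_het > 0.0
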