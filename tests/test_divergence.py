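"""Allelic divergence scan, clustering, gene proximity and windowed F_ST."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from conftest import genotype_matrix_from_codes
from foxgbs import divergence, gbs_io
from foxgbs.core import InvalidConfigError


def textbook_wc_components(n1, p1, h1, n2, p2, h2):
    """Independently coded Weir & Cockerham (1984) two-population a, b, c."""
    r = 2
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = sum(n * (p - pbar) ** 2 for n, p in ((n1, p1), (n2, p2))) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return a, b, c


class TestAllelicTest:
    def test_identical_frequencies_null(self):
        chi2, p = divergence.allelic_test(np.array([20, 20]), np.array([10, 10]))
        assert chi2 == 0 and p == 1.0

    def test_hand_computed_chi_square(self):
        # table (30,10 / 10,30): chi-square = 20, p = Pr(Chi2_1 > 20)
        chi2, p = divergence.allelic_test(np.array([30, 10]), np.array([10, 30]))
        assert chi2 == pytest.approx(20.0)
        assert p == pytest.approx(sps.chi2.sf(20.0, 1))

    def test_population_label_symmetry(self):
        c1, c2 = np.array([33, 7]), np.array([12, 28])
        _, p_ab = divergence.allelic_test(c1, c2)
        _, p_ba = divergence.allelic_test(c2, c1)
        assert p_ab == p_ba

    def test_zero_margin_untestable(self):
        chi2, p = divergence.allelic_test(np.array([40, 0]), np.array([40, 0]))
        assert chi2 == 0.0 and p == 1.0


class TestBonferroni:
    def _frame(self, p_raw, m=None):
        m = m or len(p_raw)
        return pd.DataFrame(
            {
                "locus_id": [f"L{i}" for i in range(len(p_raw))],
                "chrom": "1",
                "pos": np.arange(len(p_raw)) + 1,
                "p_adj": np.minimum(1.0, m * np.asarray(p_raw)),
            }
        )

    def test_multiplication_at_study_scale(self):
        adj = min(1.0, 48_042 * 1e-12)
        assert adj == pytest.approx(4.8042e-8)
        frame = self._frame([1e-12], m=48_042)
        sel = divergence.bonferroni_select(frame, alpha=1e-6)
        assert len(sel) == 1

    def test_monotone_and_identity(self):
        p = np.array([1e-10, 1e-8, 1e-4])
        frame = self._frame(p)
        assert (np.diff(frame.p_adj) >= 0).all()
        single = self._frame([0.01], m=1)
        assert single.p_adj[0] == pytest.approx(0.01)

    def test_invalid_alpha(self):
        with pytest.raises(InvalidConfigError):
            divergence.bonferroni_select(self._frame([0.5]), alpha=2.0)


class TestClustering:
    def test_gap_boundary_inclusive(self):
        snps = pd.DataFrame(
            {
                "chrom": ["1", "1", "2", "2"],
                "pos": [1_000_000, 3_000_000, 1_000_000, 3_000_001],
            }
        )
        rep = divergence.cluster_significant(snps)
        # exactly 2 Mb apart -> one cluster; 2,000,001 apart -> isolated
        assert rep.n_clusters == 1
        assert rep.n_clustered == 2 and rep.n_isolated == 2

    def test_order_invariance(self):
        t2 = gbs_io.load_significant_snp_table()
        a = divergence.cluster_significant(t2, chrom_col="vvu", pos_col="vvu_pos")
        shuffled = t2.sample(frac=1.0, random_state=8)
        b = divergence.cluster_significant(shuffled, chrom_col="vvu", pos_col="vvu_pos")
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_distances_match_position_differences(self):
        t2 = gbs_io.load_significant_snp_table()
        rep = divergence.cluster_significant(t2, chrom_col="vvu", pos_col="vvu_pos")
        t = rep.table
        same = t.vvu == t.vvu.shift()
        expect = t.vvu_pos - t.vvu_pos.shift()
        assert np.allclose(t.dist_prev[same], expect[same])

    def test_printed_cluster_membership_recovered(self):
        # re-derived cluster labels partition the SNPs exactly as printed
        t2 = gbs_io.load_significant_snp_table()
        rep = divergence.cluster_significant(t2, chrom_col="vvu", pos_col="vvu_pos")
        derived = rep.table.set_index("snp")["cluster"]
        printed = t2.set_index("snp")["cluster"]  # NaN marks isolated SNPs
        assert set(derived[derived > 0].index) == set(printed.dropna().index)
        # the partitions coincide: printed labels and derived ids biject
        pairs = pd.DataFrame(
            {"printed": printed.dropna(), "derived": derived[derived > 0]}
        )
        assert (pairs.groupby("derived")["printed"].nunique() == 1).all()
        assert (pairs.groupby("printed")["derived"].nunique() == 1).all()


class TestGenesNear:
    def _clusters(self):
        return pd.DataFrame(
            {"cluster": [1, 2], "chrom": ["1", "2"], "start": [1_000_000, 500], "end": [1_100_000, 900]}
        )

    def _annotation(self):
        # EXACT50K starts exactly 50 kb beyond the cluster end (inclusive);
        # TOOFAR starts one bp further and is excluded
        return pd.DataFrame(
            {
                "chrom": ["1", "1", "1"],
                "start": [1_020_000, 1_150_000, 1_150_001],
                "end": [1_030_000, 1_160_000, 1_210_000],
                "gene": ["INSIDE", "EXACT50K", "TOOFAR"],
            }
        )

    def test_inside_flank_and_boundary(self):
        out = divergence.genes_near(self._clusters(), self._annotation(), flank=50_000)
        assert out[1] == ["INSIDE", "EXACT50K"]

    def test_cluster_without_genes_empty(self):
        out = divergence.genes_near(self._clusters(), self._annotation())
        assert out[2] == []


class TestFstComponents:
    def test_null_theta_near_zero(self):
        rng = np.random.default_rng(6)
        g = rng.binomial(2, 0.5, size=(2000, 80)).astype(np.int8)
        a, b, c = divergence.fst_site_components(g[:, :40], g[:, 40:])
        assert abs(divergence.fst_weighted(a, b, c)) < 0.01

    def test_fixed_difference_theta_one(self):
        g1 = np.zeros((5, 20), dtype=np.int8)
        g2 = np.full((5, 20), 2, dtype=np.int8)
        a, b, c = divergence.fst_site_components(g1, g2)
        assert divergence.fst_weighted(a, b, c) == pytest.approx(1.0)

    def test_dual_implementation_agreement(self):
        # 1,000 random small cases against the independent transcription
        rng = np.random.default_rng(7)
        for _ in range(1000):
            n1, n2 = rng.integers(2, 30, size=2)
            g1 = rng.integers(0, 3, size=(1, n1)).astype(np.int8)
            g2 = rng.integers(0, 3, size=(1, n2)).astype(np.int8)
            a, b, c = divergence.fst_site_components(g1, g2)
            p1, h1 = g1.mean() / 2, (g1 == 1).mean()
            p2, h2 = g2.mean() / 2, (g2 == 1).mean()
            ea, eb, ec = textbook_wc_components(n1, p1, h1, n2, p2, h2)
            assert abs(a[0] - ea) < 1e-10
            assert abs(b[0] - eb) < 1e-10
            assert abs(c[0] - ec) < 1e-10

    def test_too_few_called_is_nan(self):
        g1 = np.array([[0, -1, -1]], dtype=np.int8)
        g2 = np.array([[2, 2, 2]], dtype=np.int8)
        a, _, _ = divergence.fst_site_components(g1, g2)
        assert np.isnan(a[0])


class TestFstWindows:
    def _loci(self, pos, chrom="1"):
        return pd.DataFrame(
            {
                "locus_id": [f"L{i}" for i in range(len(pos))],
                "chrom": chrom,
                "pos": pos,
            }
        )

    def test_single_snp_window_equals_site_theta(self):
        loci = self._loci([500_000])
        a, b, c = np.array([0.2]), np.array([0.1]), np.array([0.1])
        wins = divergence.fst_windows(loci, a, b, c)
        assert wins.fst.iloc[0] == pytest.approx(0.2 / 0.4)

    def test_weighted_is_ratio_of_sums_not_mean_of_ratios(self):
        loci = self._loci([100, 200])
        a = np.array([0.9, 0.0])
        b = np.array([0.0, 0.0])
        c = np.array([0.1, 3.0])
        wins = divergence.fst_windows(loci, a, b, c)
        ratio_of_sums = 0.9 / 4.0  # pools variance components across sites
        mean_of_ratios = (0.9 / 1.0 + 0.0 / 3.0) / 2
        assert wins.fst.iloc[0] == pytest.approx(ratio_of_sums)
        assert wins.fst.iloc[0] != pytest.approx(mean_of_ratios)

    def test_overlapping_windows_share_sites(self):
        pos = [600_000, 900_000, 1_400_000]
        loci = self._loci(pos)
        ones = np.ones(3)
        wins = divergence.fst_windows(loci, ones, ones, ones)
        assert wins.n_snps.sum() >= len(pos)
        # site at 600 kb belongs to windows starting at 1 and 500,001
        first_two = wins[wins.start.isin([1, 500_001])]
        assert (first_two.n_snps >= 1).all()

    def test_half_open_window_edges(self):
        loci = self._loci([1_000_000, 1_000_001])
        a, b, c = np.ones(2), np.ones(2), np.ones(2)
        wins = divergence.fst_windows(loci, a, b, c)
        w1 = wins[wins.start == 1].iloc[0]
        assert w1.n_snps == 1  # 1,000,001 is outside [1, 1,000,001)


class TestOverlapReport:
    def _windows(self):
        return pd.DataFrame(
            {
                "chrom": ["1", "1"],
                "start": [1, 2_000_001],
                "end": [1_000_001, 3_000_001],
                "n_snps": [3, 3],
                "fst": [0.7, 0.2],
                "high": [True, False],
            }
        )

    def test_disjoint_and_abutting_do_not_overlap(self):
        clusters = pd.DataFrame(
            {"cluster": [1], "chrom": ["1"], "start": [1_000_001], "end": [1_500_000]}
        )
        out = divergence.overlap_report(clusters, self._windows())
        assert out.empty  # window [1, 1,000,001) only abuts cluster start

    def test_shared_base_pair_overlaps(self):
        clusters = pd.DataFrame(
            {"cluster": [1], "chrom": ["1"], "start": [1_000_000], "end": [1_500_000]}
        )
        out = divergence.overlap_report(clusters, self._windows())
        assert len(out) == 1 and out.window_high.iloc[0]
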