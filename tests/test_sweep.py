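import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dupdiv.io import GeneRegion
from dupdiv.simulate import PopSimParams, simulate_populations
from dupdiv.sweep import (Thresholds, Window, classify_gene, classify_genes,
                          fst_hudson, nucleotide_diversity, outlier_thresholds,
                          pi_ratio, scan_windows, sliding_windows)

import oracles
from conftest import make_matrix, random_matrix


class TestSlidingWindows:
    def test_default_scan_scale_tiling(self):
        assert len(sliding_windows(100_000, 20_000, 2_000)) == 41

    def test_exact_fit_single_window(self):
        (w,) = sliding_windows(20_000, 20_000, 2_000)
        assert (w.start, w.end) == (0, 20_000)

    def test_short_chromosome_truncated(self):
        (w,) = sliding_windows(15_000, 20_000, 2_000)
        assert (w.start, w.end) == (0, 15_000)

    @settings(derandomize=True, max_examples=150, deadline=None)
    @given(length=st.integers(1, 500_000), size=st.integers(100, 50_000),
           step=st.integers(100, 10_000))
    def test_count_matches_closed_form(self, length, size, step):
        windows = sliding_windows(length, size, step)
        assert len(windows) == oracles.window_count_closed_form(length, size, step)
        # full tiling: consecutive starts differ by step, all within bounds
        starts = [w.start for w in windows]
        assert starts[0] == 0
        assert all(b - a == step for a, b in zip(starts, starts[1:]))


class TestNucleotideDiversity:
    def test_two_haplotypes_one_difference(self):
        # one diploid heterozygous at 1 of 100 bp
        m = make_matrix([[1]], positions=[50], chrom_length=100)
        assert nucleotide_diversity(m, "wild", Window("chr1", 0, 100)) == pytest.approx(0.01)

    def test_monomorphic_window(self):
        m = make_matrix([[0, 0], [2, 2]], positions=[1, 2], chrom_length=10)
        assert nucleotide_diversity(m, "wild", Window("chr1", 0, 10)) == 0.0

    def test_four_haplotypes_balanced_site(self):
        m = make_matrix([[2, 0]], positions=[4], chrom_length=10)
        pi = nucleotide_diversity(m, "wild", Window("chr1", 0, 10))
        assert pi == pytest.approx((4 / 3) * 0.5 / 10)
        assert pi == pytest.approx((4 / 6) / 10)  # 4 of 6 haplotype pairs differ

    def test_matches_bruteforce_on_random_matrices(self, rng):
        for _ in range(20):
            m = random_matrix(rng)
            expected = oracles.pi_bruteforce(m.calls, m.positions, 0, 1000)
            got = nucleotide_diversity(m, "wild", Window("chr1", 0, 1000))
            assert got == pytest.approx(expected, abs=1e-12)

    def test_unknown_population_errors(self):
        m = make_matrix([[1]], chrom_length=10)
        with pytest.raises(ValueError, match="no samples"):
            nucleotide_diversity(m, "landrace", Window("chr1", 0, 10))


class TestPiRatio:
    def test_plain_ratio(self):
        assert pi_ratio(0.004, 0.001, pseudocount=0.0) == pytest.approx(4.0)

    def test_equal_pi(self):
        assert pi_ratio(0.002, 0.002, pseudocount=0.0) == pytest.approx(1.0)

    def test_zero_denominator_with_pseudocount_is_finite(self):
        r = pi_ratio(0.004, 0.0, pseudocount=1e-6)
        assert np.isfinite(r)

    def test_both_zero_no_pseudocount_is_flagged(self):
        assert np.isnan(pi_ratio(0.0, 0.0, pseudocount=0.0))


class TestFst:
    def test_fixed_difference(self):
        calls = np.array([[2, 2, 0, 0]], dtype=np.int8)
        m = make_matrix(calls, positions=[5], pops=["a", "a", "b", "b"], chrom_length=10)
        assert fst_hudson(m, "a", "b", Window("chr1", 0, 10)) == pytest.approx(1.0)

    def test_hand_computed_single_site(self):
        # p_a=0.8, p_b=0.2, 10 haploid copies each
        calls = np.array([[2, 2, 2, 1, 1, 0, 0, 0, 1, 1]], dtype=np.int8)
        pops = ["a"] * 5 + ["b"] * 5
        m = make_matrix(calls, positions=[5], pops=pops, chrom_length=10)
        fst = fst_hudson(m, "a", "b", Window("chr1", 0, 10))
        assert fst == pytest.approx(1 - (2 * 0.8 * 0.2 * 10 / 9) / 0.68, abs=1e-12)
        assert fst == pytest.approx(oracles.hudson_fst_oracle(0.8, 0.2, 10, 10), abs=1e-12)
        assert fst == pytest.approx(0.4771, abs=1e-4)

    def test_null_differentiation_near_zero(self):
        rng = np.random.default_rng(0)
        fsts = []
        for seed in range(5):
            p = PopSimParams(chrom_length=100_000, seed=seed,
                             bottleneck_landrace=0.0, bottleneck_improved=0.0,
                             n_wild=40, n_landrace=40, n_improved=40)
            m = simulate_populations(p)
            fsts.append(fst_hudson(m, "wild", "landrace", Window("chr1", 0, 100_000)))
        assert max(abs(f) for f in fsts) < 0.05

    def test_no_usable_sites_flagged(self):
        calls = np.array([[-1, -1, 1, 1]], dtype=np.int8)
        m = make_matrix(calls, positions=[5], pops=["a", "a", "b", "b"], chrom_length=10)
        assert np.isnan(fst_hudson(m, "a", "b", Window("chr1", 0, 10)))


class TestThresholds:
    def test_top5_of_1_to_100(self):
        thr = outlier_thresholds(np.arange(1, 101), (0.95,))
        values = np.arange(1, 101)
        outliers = values[values >= thr.cutoffs[0.95]]
        assert list(outliers) == [96, 97, 98, 99, 100]

    def test_degenerate_all_equal_flagged(self):
        thr = outlier_thresholds(np.full(50, 3.3))
        assert thr.degenerate

    def test_too_few_windows_errors(self):
        with pytest.raises(ValueError, match="20"):
            outlier_thresholds(np.arange(10))

    def test_top1_subset_of_top5(self, rng):
        values = rng.normal(size=200)
        thr = outlier_thresholds(values, (0.95, 0.99))
        top1 = set(np.where(values >= thr.cutoffs[0.99])[0])
        top5 = set(np.where(values >= thr.cutoffs[0.95])[0])
        assert top1 <= top5


def _toy_window_stats(ratio_dom, ratio_imp):
    n = len(ratio_dom)
    return pd.DataFrame({
        "chrom": "chr1",
        "start": np.arange(n) * 2_000,
        "end": np.arange(n) * 2_000 + 20_000,
        "n_snps": 10,
        "ratio_dom": ratio_dom,
        "ratio_imp": ratio_imp,
        "evaluated": True,
    })


class TestClassification:
    def test_three_gene_patterns(self):
        # 100 windows; top-1% improvement peaks at windows 10-12 and 50-52;
        # domestication signal at 50-52 above the 95th but below the 99th
        # percentile (two higher decoy windows at 80-81 set the top-1% cutoff)
        rng = np.random.default_rng(1)
        dom = 1 + 0.01 * rng.random(100)
        imp = 1 + 0.01 * rng.random(100)
        imp[10:13] = 50.0
        imp[50:53] = 50.0
        dom[50:53] = 1.02
        dom[80:82] = 2.0
        stats = _toy_window_stats(dom, imp)
        genes = [
            GeneRegion("chr1", 21_000, 23_000, "improvement_only"),
            GeneRegion("chr1", 101_000, 103_000, "both"),
            GeneRegion("chr1", 150_000, 152_000, "neither"),
        ]
        calls = classify_genes(stats, genes)
        assert (calls[0].domestication_tier, calls[0].improvement_tier) == ("none", "top1")
        assert (calls[1].domestication_tier, calls[1].improvement_tier) == ("top5", "top1")
        assert (calls[2].domestication_tier, calls[2].improvement_tier) == ("none", "none")

    def test_gene_without_evaluated_window_is_none(self):
        stats = _toy_window_stats(np.linspace(1, 2, 50), np.linspace(1, 2, 50))
        stats.loc[stats.index[:5], "evaluated"] = False
        thr = Thresholds({0.95: 1.9, 0.99: 1.99}, 45, False)
        gene = GeneRegion("chr1", 0, 1_000, "nocov")  # overlaps only unevaluated windows
        call = classify_gene(gene, stats, thr, thr)
        assert (call.domestication_tier, call.improvement_tier) == ("none", "none")
        assert call.n_windows == 0

    def test_degenerate_distribution_emits_no_calls(self):
        stats = _toy_window_stats(np.ones(50), np.ones(50))
        calls = classify_genes(stats, [GeneRegion("chr1", 0, 5_000, "g")])
        assert (calls[0].domestication_tier, calls[0].improvement_tier) == ("none", "none")


class TestScanWindows:
    def test_schema_and_consistency_with_pointwise_functions(self):
        p = PopSimParams(chrom_length=100_000, seed=2, n_wild=10, n_landrace=10,
                         n_improved=10)
        m = simulate_populations(p)
        df = scan_windows(m)
        assert len(df) == 41
        expected_cols = {"chrom", "start", "end", "n_snps", "pi_wild", "pi_landrace",
                         "pi_improved", "ratio_dom", "ratio_imp",
                         "fst_wild_landrace", "fst_landrace_improved", "evaluated"}
        assert expected_cols <= set(df.columns)
        # spot-check one window against the standalone functions
        row = df.iloc[7]
        w = Window("chr1", int(row["start"]), int(row["end"]))
        assert row["pi_wild"] == pytest.approx(nucleotide_diversity(m, "wild", w), abs=1e-12)
        assert row["fst_wild_landrace"] == pytest.approx(
            fst_hudson(m, "wild", "landrace", w), abs=1e-12)
        assert row["ratio_dom"] == pytest.approx(
            pi_ratio(row["pi_wild"], row["pi_landrace"]), abs=1e-12)

    def test_orientation_flag_inverts_ratios(self):
        p = PopSimParams(chrom_length=60_000, seed=4, n_wild=8, n_landrace=8, n_improved=8)
        m = simulate_populations(p)
        a = scan_windows(m, orientation="ancestral-over-derived")
        b = scan_windows(m, orientation="derived-over-ancestral")
        c = 1e-6
        np.testing.assert_allclose(
            (a["pi_wild"] + c) / (a["pi_landrace"] + c), a["ratio_dom"])
        np.testing.assert_allclose(
            (b["pi_landrace"] + c) / (b["pi_wild"] + c), b["ratio_dom"])

    def test_low_snp_windows_flagged_unevaluated(self):
        m = make_matrix(np.ones((2, 4), dtype=np.int8), positions=[100, 200],
                        pops=["wild", "landrace", "improved", "wild"],
                        chrom_length=50_000)
        df = scan_windows(m, min_snps=3)
        assert not df["evaluated"].any()
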