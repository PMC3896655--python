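import numpy as np
import pytest

import clinescan as cs


def scan_of(bf, p=None, ids=None):
    bf = np.asarray(bf, dtype=float).reshape(-1, 1)
    L = bf.shape[0]
    return cs.ScanResult(
        snp_ids=ids or [f"s{i}" for i in range(L)],
        var_names=["v"],
        log10_bf=bf,
        empirical_p=None if p is None else np.asarray(p, dtype=float).reshape(-1, 1),
    )


class TestCorrelations:
    def test_self_correlation_is_one(self):
        a = scan_of([1.0, 2.0, 3.0])
        assert cs.log_bf_correlation(a, a, "v") == pytest.approx(1.0)

    def test_negated_run_gives_minus_one(self):
        a = scan_of([1.0, 2.0, 3.0])
        b = scan_of([-1.0, -2.0, -3.0])
        assert cs.log_bf_correlation(a, b, "v") == pytest.approx(-1.0)

    def test_closed_form_value(self):
        a = scan_of([1.0, 2.0, 3.0])
        b = scan_of([1.0, 2.0, 4.0])
        assert cs.log_bf_correlation(a, b, "v") == pytest.approx(0.9820, abs=5e-5)

    def test_zero_variance_fails(self):
        a = scan_of([1.0, 1.0, 1.0])
        b = scan_of([1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="variance"):
            cs.log_bf_correlation(a, b, "v")

    def test_pvalue_correlation_mirrors_log_bf(self):
        a = scan_of([1.0, 2.0, 3.0], p=[0.75, 0.5, 0.25])
        assert cs.pvalue_correlation(a, a, "v") == pytest.approx(1.0)

    def test_misaligned_snp_sets_fail(self):
        a = scan_of([1.0, 2.0])
        b = scan_of([1.0, 2.0], ids=["x", "y"])
        with pytest.raises(ValueError, match="same SNPs"):
            cs.log_bf_correlation(a, b, "v")


class TestAveragePairwise:
    def test_two_runs_give_the_single_pair(self):
        a, b = scan_of([1.0, 2.0, 3.0]), scan_of([1.0, 2.0, 4.0])
        got = cs.average_pairwise_correlations([a, b])
        assert got[0] == pytest.approx(cs.log_bf_correlation(a, b, "v"))

    def test_three_identical_runs_give_one(self):
        a = scan_of([1.0, 2.0, 3.0])
        assert cs.average_pairwise_correlations([a, a, a])[0] == pytest.approx(1.0)

    def test_mean_over_pairs(self):
        # three runs engineered so pair correlations average like plain numbers
        rng = np.random.default_rng(5)
        runs = [scan_of(rng.standard_normal(50)) for _ in range(3)]
        rs = [
            cs.log_bf_correlation(runs[i], runs[j], "v")
            for i, j in [(0, 1), (0, 2), (1, 2)]
        ]
        assert cs.average_pairwise_correlations(runs)[0] == pytest.approx(np.mean(rs))

    def test_fewer_than_two_runs_fail(self):
        with pytest.raises(ValueError, match="2 runs"):
            cs.average_pairwise_correlations([scan_of([1.0, 2.0])])


class TestTailOverlap:
    def test_identical_runs_full_overlap(self):
        p = np.array([0.01, 0.2, 0.5, 0.9])
        assert cs.tail_overlap(p, p, 0.05, 0.05) == 1.0

    def test_disjoint_tails(self):
        pA = np.array([0.01, 0.9, 0.9, 0.9])
        pB = np.array([0.9, 0.01, 0.9, 0.9])
        assert cs.tail_overlap(pA, pB, 0.05, 0.05) == 0.0

    def test_monotone_in_partner_cutoff(self):
        # with the fixed tail the smaller of the two, widening the partner
        # tail can only add overlapping SNPs over a fixed denominator
        rng = np.random.default_rng(2)
        pA, pB = rng.uniform(size=500), rng.uniform(size=500)
        vals = [cs.tail_overlap(pA, pB, 0.05, c) for c in (0.05, 0.2, 0.5, 0.9)]
        assert vals == sorted(vals)

    def test_symmetric_under_swap(self):
        rng = np.random.default_rng(3)
        pA, pB = rng.uniform(size=300), rng.uniform(size=300)
        assert cs.tail_overlap(pA, pB, 0.01, 0.1) == cs.tail_overlap(pB, pA, 0.1, 0.01)

    def test_empty_tail_gives_zero(self):
        p = np.array([0.5, 0.9])
        assert cs.tail_overlap(p, p, 0.01, 0.5) == 0.0

    def test_matrix_diagonal_one_against_self(self):
        # enough SNPs that every default cutoff tail is nonempty
        rng = np.random.default_rng(4)
        L = 10_000
        run = scan_of(rng.standard_normal(L), p=rng.permutation(np.arange(1, L + 1)) / L)
        mat = cs.tail_overlap_matrix(run, run)
        np.testing.assert_allclose(np.diag(mat.proportions), 1.0)
        assert np.all((mat.proportions >= 0) & (mat.proportions <= 1))

    def test_independent_runs_match_analytic_expectation(self):
        # under independence, overlap at equal cutoffs c concentrates near c
        rng = np.random.default_rng(6)
        L = 200_000
        pA, pB = rng.uniform(size=L), rng.uniform(size=L)
        got = cs.tail_overlap(pA, pB, 0.05, 0.05)
        se = np.sqrt(0.05 * 0.95 / (0.05 * L))
        assert abs(got - 0.05) < 3 * se


class TestRankedBinOverlap:
    def test_identical_runs_give_all_ones(self):
        rng = np.random.default_rng(7)
        run = scan_of(rng.standard_normal(3000), p=rng.uniform(size=3000))
        np.testing.assert_allclose(cs.ranked_bin_overlap(run, run), 1.0)

    def test_reversed_ranking_has_empty_first_bin(self):
        p = np.linspace(0.001, 1.0, 2000)
        a = scan_of(np.zeros(2000) + np.arange(2000), p=p)
        b = scan_of(np.zeros(2000) + np.arange(2000), p=p[::-1].copy())
        got = cs.ranked_bin_overlap(a, b)
        assert got[0] == 0.0

    def test_independent_rankings_near_hypergeometric_mean(self):
        rng = np.random.default_rng(8)
        L, bs = 50_000, 1000
        a = scan_of(np.zeros(L), p=rng.permutation(np.arange(1, L + 1)) / L)
        b = scan_of(np.zeros(L), p=rng.permutation(np.arange(1, L + 1)) / L)
        got = cs.ranked_bin_overlap(a, b, bin_size=bs)
        exp = bs / L
        se = np.sqrt(bs * exp * (1 - exp)) / bs
        mid = got[len(got) // 2]
        assert abs(mid - exp) < 4 * se

    def test_too_few_snps_fail(self):
        run = scan_of(np.arange(10.0), p=np.linspace(0.1, 1, 10))
        with pytest.raises(ValueError, match="bin_size"):
            cs.ranked_bin_overlap(run, run, bin_size=100)


class TestAverageRuns:
    def test_identical_runs_unchanged(self):
        run = scan_of([1.0, 2.0, 3.0])
        avg = cs.average_runs([run, run])
        np.testing.assert_allclose(avg.log10_bf, run.log10_bf)

    def test_mean_of_log_bfs(self):
        a, b = scan_of([1.0, 0.0]), scan_of([3.0, 0.0])
        assert cs.average_runs([a, b]).log10_bf[0, 0] == 2.0

    def test_shape_preserved_and_p_dropped(self):
        rng = np.random.default_rng(9)
        runs = [scan_of(rng.standard_normal(20), p=rng.uniform(size=20)) for _ in range(3)]
        avg = cs.average_runs(runs)
        assert avg.log10_bf.shape == (20, 1)
        assert avg.empirical_p is None

    def test_single_run_fails(self):
        with pytest.raises(ValueError, match="2 runs"):
            cs.average_runs([scan_of([1.0, 2.0])])


class TestPairedWilcoxon:
    def test_constant_positive_shift_gives_extreme_p(self):
        # 11 all-positive differences: the most extreme sign-rank outcome
        a = np.linspace(0.5, 0.9, 11)
        got = cs.paired_wilcoxon_correlations(a, a + 0.05)
        assert got == pytest.approx(2 / 2**11)

    def test_all_zero_differences_fail(self):
        a = np.linspace(0.5, 0.9, 11)
        with pytest.raises(ValueError, match="degenerate"):
            cs.paired_wilcoxon_correlations(a, a)

    def test_null_calibration_over_seeded_replicates(self):
        # random paired differences: should rarely look significant
        rng = np.random.default_rng(10)
        nonsig = 0
        for _ in range(100):
            a = rng.uniform(0.5, 0.9, size=11)
            b = a + rng.choice([-1, 1], size=11) * rng.uniform(0.01, 0.05, size=11)
            nonsig += cs.paired_wilcoxon_correlations(a, b) > 0.05
        assert nonsig >= 90
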