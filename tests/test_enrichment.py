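import numpy as np
import pytest

import clinescan as cs
from clinescan.types import GeneIntervals, GenicLabels


def genes_at(intervals, chrom="chr1"):
    return GeneIntervals(
        chrom=np.array([chrom] * len(intervals), dtype=object),
        start=np.array([s for s, _ in intervals], dtype=np.int64),
        end=np.array([e for _, e in intervals], dtype=np.int64),
    )


class TestClassifyGenic:
    def test_distance_thresholds(self):
        genes = genes_at([(100_000, 120_000)])
        pos = np.array([110_000, 150_000, 125_000, 181_000, 50_000])
        chrom = np.array(["chr1"] * 5, dtype=object)
        labels = cs.classify_genic(chrom, pos, genes)
        # inside; 30 kb away; 5 kb away; >60 kb away; 50 kb away exactly
        assert labels.labels.tolist() == [
            "genic", "ambiguous", "genic", "nongenic", "ambiguous",
        ]

    def test_chromosome_without_genes_is_nongenic(self):
        genes = genes_at([(0, 1000)], chrom="chr2")
        labels = cs.classify_genic(np.array(["chr1"], dtype=object), np.array([500]), genes)
        assert labels.labels.tolist() == ["nongenic"]

    def test_overlapping_intervals_handled(self):
        genes = genes_at([(0, 50_000), (10_000, 20_000)])
        labels = cs.classify_genic(
            np.array(["chr1"] * 2, dtype=object), np.array([30_000, 55_000]), genes
        )
        assert labels.labels.tolist() == ["genic", "genic"]

    def test_bad_thresholds_fail(self):
        genes = genes_at([(0, 100)])
        with pytest.raises(ValueError, match="near"):
            cs.classify_genic(
                np.array(["chr1"], dtype=object), np.array([1]), genes, near=50_000, far=10_000
            )


def labels_of(lst):
    return GenicLabels(labels=np.array(lst, dtype=object))


class TestEnrichmentStatistic:
    def test_formula(self):
        # n_g=20, n_ng=10 in tail; N_g=1000, N_ng=2000 overall -> 4.0
        lab = np.array(["genic"] * 1000 + ["nongenic"] * 2000, dtype=object)
        tail = np.zeros(3000, dtype=bool)
        tail[:20] = True  # genic tail members
        tail[1000:1010] = True  # nongenic tail members
        res = cs.enrichment_statistic(GenicLabels(labels=lab), tail)
        assert res.enrichment == pytest.approx(4.0)
        assert (res.n_g, res.n_ng, res.N_g, res.N_ng) == (20, 10, 1000, 2000)

    def test_tail_matching_genome_ratio_gives_one(self):
        lab = np.array(["genic"] * 100 + ["nongenic"] * 200, dtype=object)
        tail = np.zeros(300, dtype=bool)
        tail[:10] = True
        tail[100:120] = True
        assert cs.enrichment_statistic(GenicLabels(labels=lab), tail).enrichment == 1.0

    def test_empty_genic_tail_gives_zero(self):
        lab = np.array(["genic"] * 100 + ["nongenic"] * 200, dtype=object)
        tail = np.zeros(300, dtype=bool)
        tail[100:105] = True
        assert cs.enrichment_statistic(GenicLabels(labels=lab), tail).enrichment == 0.0

    def test_invariant_to_duplication(self):
        lab = np.array(["genic"] * 50 + ["nongenic"] * 70, dtype=object)
        rng = np.random.default_rng(0)
        tail = rng.random(120) < 0.2
        one = cs.enrichment_statistic(GenicLabels(labels=lab), tail).enrichment
        two = cs.enrichment_statistic(
            GenicLabels(labels=np.concatenate([lab, lab])), np.concatenate([tail, tail])
        ).enrichment
        assert one == pytest.approx(two)

    def test_ambiguous_excluded_from_all_counts(self):
        lab = np.array(["genic", "ambiguous", "nongenic", "ambiguous"], dtype=object)
        tail = np.array([True, True, True, False])
        res = cs.enrichment_statistic(GenicLabels(labels=lab), tail)
        assert (res.n_g, res.n_ng, res.N_g, res.N_ng) == (1, 1, 1, 1)


class TestStars:
    @pytest.mark.parametrize(
        "frac,expected",
        [
            (0.90, 0),
            (0.96, 1),
            (0.995, 3),
            (0.95, 1),
            (0.9749, 1),
            (0.975, 2),
            (0.9899, 2),
            (0.99, 3),
            (1.0, 3),
            (0.0, 0),
        ],
    )
    def test_star_map(self, frac, expected):
        assert cs.stars(frac) == expected

    def test_out_of_range_fails(self):
        with pytest.raises(ValueError):
            cs.stars(1.2)


class TestBlockBootstrap:
    def make_inputs(self, seed=0, L=2000):
        rng = np.random.default_rng(seed)
        pos = rng.integers(0, 50_000_000, size=L)
        chrom = np.array(["chr1"] * L, dtype=object)
        lab = np.array(
            rng.choice(["genic", "nongenic"], size=L, p=[0.4, 0.6]), dtype=object
        )
        p = rng.permutation(np.arange(1, L + 1)) / L
        return p, GenicLabels(labels=lab), chrom, pos

    def test_deterministic_given_seed(self):
        p, lab, chrom, pos = self.make_inputs()
        a = cs.block_bootstrap_significance(p, lab, chrom, pos, 0.05, reps=200, seed=42)
        b = cs.block_bootstrap_significance(p, lab, chrom, pos, 0.05, reps=200, seed=42)
        assert a.enriched_fraction == b.enriched_fraction

    def test_all_nongenic_tail_gives_zero_fraction_and_stars(self):
        L = 1000
        rng = np.random.default_rng(1)
        pos = rng.integers(0, 10_000_000, size=L)
        chrom = np.array(["chr1"] * L, dtype=object)
        lab = np.array(["genic"] * 500 + ["nongenic"] * 500, dtype=object)
        p = np.ones(L)
        p[500:550] = 0.01  # tail entirely non-genic
        res = cs.block_bootstrap_significance(p, GenicLabels(labels=lab), chrom, pos, 0.05, reps=300, seed=2)
        assert res.enriched_fraction == 0.0
        assert res.stars == 0

    def test_doubling_reps_changes_fraction_slowly(self):
        p, lab, chrom, pos = self.make_inputs(seed=3)
        ok = 0
        for s in range(10):
            a = cs.block_bootstrap_significance(p, lab, chrom, pos, 0.05, reps=400, seed=s).enriched_fraction
            b = cs.block_bootstrap_significance(p, lab, chrom, pos, 0.05, reps=800, seed=s + 100).enriched_fraction
            ok += abs(a - b) < 3 / np.sqrt(400)
        assert ok >= 9

    def test_reps_below_one_fail(self):
        p, lab, chrom, pos = self.make_inputs()
        with pytest.raises(ValueError, match="reps"):
            cs.block_bootstrap_significance(p, lab, chrom, pos, 0.05, reps=0)

    def test_null_enrichment_mean_near_one(self):
        # labels independent of p: average enrichment over many tails ~ 1
        rng = np.random.default_rng(4)
        vals = []
        for s in range(40):
            p, lab, chrom, pos = self.make_inputs(seed=s, L=1500)
            vals.append(cs.enrichment_statistic(lab, p <= 0.1).enrichment)
        se = np.std(vals) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - 1.0) < 3 * se + 1e-9
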