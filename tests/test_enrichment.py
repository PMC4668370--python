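"""Permutation enrichment: observed statistic, null, ratio, p-values."""

import numpy as np
import pytest
from scipy import stats

from hmcdiff import (
    AnnotationSet,
    ChromSizes,
    EnrichmentResult,
    GenomicInterval,
    Peak,
    SimulationConfig,
    average_replicates,
    enrichment_test,
    expected_tags,
    make_genome,
    make_peaks_and_tags,
    observed_tags,
)

from conftest import brute_force_observed, random_micro_instance


def peak(start, end, tags, chrom="chr1"):
    return Peak(GenomicInterval(chrom, start, end), tags)


class TestObservedTags:
    def test_hand_evaluated_intersection(self):
        ann = AnnotationSet.build("a", [GenomicInterval("chr1", 160, 300)])
        assert observed_tags([peak(100, 200, 50)], ann) == pytest.approx(20.0)

    def test_full_genome_cover_gives_total_tags(self, small_sizes):
        ann = AnnotationSet.build(
            "all", [GenomicInterval(c, 0, small_sizes[c]) for c in small_sizes]
        )
        peaks = [peak(0, 100, 10), peak(500, 700, 3), peak(10, 40, 5, chrom="chr2")]
        assert observed_tags(peaks, ann) == pytest.approx(18.0)

    def test_disjoint_peak_contributes_zero(self):
        ann = AnnotationSet.build("a", [GenomicInterval("chr1", 1000, 2000)])
        assert observed_tags([peak(0, 100, 50)], ann) == 0.0

    def test_matches_per_base_oracle_on_micro_genomes(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            _, peaks, ann = random_micro_instance(rng)
            fast = observed_tags(peaks, ann)
            slow = brute_force_observed(peaks, ann)
            assert fast == pytest.approx(slow, rel=1e-9, abs=1e-9)

    def test_partition_conserves_total_tags(self, small_sizes):
        # annotations that partition the genome must split the tag mass exactly
        rng = np.random.default_rng(8)
        peaks = []
        for _ in range(30):
            s = int(rng.integers(0, 99_000))
            peaks.append(peak(s, s + int(rng.integers(10, 800)), int(rng.integers(1, 60))))
        left = AnnotationSet.build("left", [GenomicInterval("chr1", 0, 40_000)])
        right = AnnotationSet.build(
            "right",
            [GenomicInterval("chr1", 40_000, 100_000), GenomicInterval("chr2", 0, 50_000)],
        )
        total = sum(p.tags for p in peaks)
        assert observed_tags(peaks, left) + observed_tags(peaks, right) == pytest.approx(total)


class TestExpectedTags:
    def test_full_cover_mean_exact_sd_zero(self, small_sizes):
        ann = AnnotationSet.build(
            "all", [GenomicInterval(c, 0, small_sizes[c]) for c in small_sizes]
        )
        peaks = [peak(0, 100, 10), peak(500, 700, 30)]
        mean, sd, null = expected_tags(peaks, ann, small_sizes, n_shuffles=20, seed=0)
        assert mean == pytest.approx(40.0)
        assert sd == pytest.approx(0.0)

    def test_determinism(self, small_sizes):
        ann = AnnotationSet.build("a", [GenomicInterval("chr1", 0, 30_000)])
        peaks = [peak(0, 500, 10), peak(5_000, 5_800, 4)]
        a = expected_tags(peaks, ann, small_sizes, n_shuffles=50, seed=3)
        b = expected_tags(peaks, ann, small_sizes, n_shuffles=50, seed=3)
        assert a[0] == b[0] and a[1] == b[1] and np.array_equal(a[2], b[2])

    def test_mean_matches_annotation_fraction(self, small_sizes):
        # annotation covering fraction f of the genome catches ~f of tag mass
        ann = AnnotationSet.build("a", [GenomicInterval("chr1", 0, 30_000)])
        f = 30_000 / small_sizes.total
        rng = np.random.default_rng(9)
        peaks = []
        for _ in range(100):
            s = int(rng.integers(0, 99_900))
            peaks.append(peak(s, s + 50, int(rng.integers(1, 20))))
        total = sum(p.tags for p in peaks)
        n_shuffles = 400
        mean, sd, _ = expected_tags(peaks, ann, small_sizes, n_shuffles=n_shuffles, seed=1)
        assert abs(mean - f * total) <= 3 * sd / np.sqrt(n_shuffles) + 1e-9


class TestEnrichmentTest:
    def test_all_peaks_inside_small_annotation(self):
        sizes = ChromSizes({"chr1": 1_000_000})
        ann = AnnotationSet.build("a", [GenomicInterval("chr1", 0, 50_000)])  # f = 0.05
        rng = np.random.default_rng(2)
        peaks = []
        for _ in range(80):
            s = int(rng.integers(0, 49_500))
            peaks.append(peak(s, s + 400, int(rng.integers(5, 50))))
        res = enrichment_test(peaks, ann, sizes, n_shuffles=1000, seed=4)
        assert res.enrichment == pytest.approx(20.0, rel=0.15)  # ~1/f
        assert res.p_empirical == pytest.approx(1 / 1001)
        assert res.p_empirical < 0.001

    def test_uniform_peaks_enrichment_near_one(self):
        cfg = SimulationConfig(seed=12, n_peaks=800, chrom_lengths=(600_000, 400_000),
                               n_genes=60, gene_length_median=3_000, n_islands=30)
        genome = make_genome(cfg)
        peaks, _, _ = make_peaks_and_tags(cfg, genome.sizes)
        res = enrichment_test(peaks, genome.islands, genome.sizes, n_shuffles=300, seed=5)
        assert res.enrichment == pytest.approx(1.0, abs=0.15)

    def test_empty_expected_flags_undefined_ratio(self):
        sizes = ChromSizes({"chr1": 2_000, "chr2": 500})
        ann = AnnotationSet.build("a", [GenomicInterval("chr2", 0, 500)])
        # a peak longer than chr2 can never land there, so the null mass is 0
        peaks = [peak(0, 1_000, 10)]
        res = enrichment_test(peaks, ann, sizes, n_shuffles=30, seed=0)
        assert res.expected == 0.0
        assert np.isnan(res.enrichment)
        assert 0 < res.p_empirical <= 1

    def test_null_pvalues_approximately_uniform(self):
        # uniform placement: the empirical p over many datasets is ~U(0,1)
        sizes = ChromSizes({"chr1": 50_000})
        ann = AnnotationSet.build("a", [GenomicInterval("chr1", 10_000, 20_000)])
        pvals = []
        for ds in range(200):
            rng = np.random.default_rng(1_000 + ds)
            peaks = []
            for _ in range(20):
                s = int(rng.integers(0, 49_800))
                peaks.append(peak(s, s + 150, int(rng.integers(1, 40))))
            res = enrichment_test(peaks, ann, sizes, n_shuffles=50, seed=2_000 + ds)
            pvals.append(res.p_empirical)
        d, p = stats.kstest(pvals, "uniform")
        assert p > 1e-3

    def test_enrichment_monotone_in_planted_fraction(self):
        cfg0 = SimulationConfig(seed=3, n_islands=60, island_width_median=2_500,
                                island_width_sigma=0.1, n_peaks=300)
        genome = make_genome(cfg0)
        means = []
        for q in (0.1, 0.4, 0.8):
            vals = []
            for seed in range(3):
                cfg = SimulationConfig(
                    seed=100 + seed, annotation_enrichment=q, n_islands=60,
                    island_width_median=2_500, island_width_sigma=0.1, n_peaks=300,
                )
                peaks, _, _ = make_peaks_and_tags(cfg, genome.sizes, genome.islands)
                res = enrichment_test(peaks, genome.islands, genome.sizes,
                                      n_shuffles=100, seed=seed)
                vals.append(res.enrichment)
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]


class TestAverageReplicates:
    def _result(self, enrichment, name="a"):
        return EnrichmentResult(name, 1, 1, 0, enrichment, 0.5, 0.5, 10)

    def test_hand_arithmetic(self):
        mean, sd = average_replicates([self._result(2.0), self._result(4.0)])
        assert mean == pytest.approx(3.0)
        assert sd == pytest.approx(np.sqrt(2))

    def test_single_replicate_sd_zero(self):
        assert average_replicates([self._result(2.5)]) == (2.5, 0.0)

    def test_empty_and_mixed_annotations_rejected(self):
        with pytest.raises(ValueError):
            average_replicates([])
        with pytest.raises(ValueError, match="mix"):
            average_replicates([self._result(1.0, "a"), self._result(2.0, "b")])
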