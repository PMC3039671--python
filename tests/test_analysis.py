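import numpy as np
import pytest

from broadcall import (
    GeneModel,
    GenomicInterval,
    PeakRegion,
    Pwm,
    TagSet,
    classify_location,
    finger_domain_association,
    fold_coverage_difference,
    intersect_sets,
    mean_max_height,
    motif_density,
    nearest_gene,
    repeat_fraction_histogram,
    scan_pwm,
    tag_density_per_kb,
    top_decile_ratio,
)
from conftest import random_intervals


def overlap(a, b):
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


class TestIntersectSets:
    def test_simple_overlap(self):
        a = [GenomicInterval("chr1", 0, 100)]
        b = [GenomicInterval("chr1", 50, 150)]
        result = intersect_sets(a, b, 1)
        assert (result.a_only, result.b_only, result.both) == (0, 0, 1)

    def test_disjoint_sets(self):
        a = [GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 500, 600)]
        b = [GenomicInterval("chr1", 200, 300)]
        result = intersect_sets(a, b, 1)
        assert (result.a_only, result.b_only, result.both) == (2, 1, 0)

    def test_min_overlap_gate(self):
        a = [GenomicInterval("chr1", 0, 100)]
        b = [GenomicInterval("chr1", 95, 200)]
        assert intersect_sets(a, b, 10).both == 0
        assert intersect_sets(a, b, 5).both == 1

    def test_matches_all_pairs_oracle(self, rng):
        a = random_intervals(rng, 2000, extent=500_000)
        b = random_intervals(rng, 2000, extent=500_000)
        min_overlap = 50
        result = intersect_sets(a, b, min_overlap)
        a_hits = sum(any(overlap(x, y) >= min_overlap for y in b) for x in a)
        b_hits = sum(any(overlap(x, y) >= min_overlap for y in a) for x in b)
        assert result.a_both == a_hits
        assert result.b_both == b_hits
        assert result.a_only == len(a) - a_hits
        assert result.b_only == len(b) - b_hits

    def test_symmetry(self, rng):
        a = random_intervals(rng, 300, extent=100_000)
        b = random_intervals(rng, 300, extent=100_000)
        ab = intersect_sets(a, b, 25)
        ba = intersect_sets(b, a, 25)
        assert (ab.a_only, ab.b_only, ab.both) == (ba.b_only, ba.a_only, ba.both)


class TestTagDensity:
    def make_tags(self, positions, chrom="chr1", extent=100_000):
        pos = np.asarray(positions, dtype=np.int64)
        return TagSet(
            {chrom: (pos, np.ones(pos.size, dtype=np.int8))},
            chrom_sizes={chrom: extent},
        )

    def test_ten_tags_in_two_kb(self):
        tags = self.make_tags(np.arange(1000, 2000, 100))
        per_region, aggregate = tag_density_per_kb(
            tags, [GenomicInterval("chr1", 500, 2500)]
        )
        assert per_region == [5.0]
        assert aggregate == 5.0

    def test_no_tags_zero_everywhere(self):
        tags = self.make_tags([])
        per_region, aggregate = tag_density_per_kb(
            tags, [GenomicInterval("chr1", 0, 1000)]
        )
        assert per_region == [0.0] and aggregate == 0.0

    def test_matches_membership_oracle(self, rng):
        pos = np.sort(rng.integers(0, 200_000, size=5000))
        tags = self.make_tags(pos, extent=200_000)
        regions = random_intervals(rng, 100, extent=190_000)
        per_region, aggregate = tag_density_per_kb(tags, regions)
        for region, density in zip(regions, per_region):
            count = sum(region.start <= p < region.end for p in pos)
            assert density == pytest.approx(count * 1000 / region.length())
        total = sum(sum(r.start <= p < r.end for p in pos) for r in regions)
        assert aggregate == pytest.approx(
            total * 1000 / sum(r.length() for r in regions)
        )

    def test_split_invariance_of_aggregate(self):
        tags = self.make_tags(np.arange(0, 10_000, 7))
        whole = [GenomicInterval("chr1", 1000, 9000)]
        halves = [GenomicInterval("chr1", 1000, 5000), GenomicInterval("chr1", 5000, 9000)]
        assert tag_density_per_kb(tags, whole)[1] == pytest.approx(
            tag_density_per_kb(tags, halves)[1]
        )

    def test_empty_region_list_rejected(self):
        with pytest.raises(ValueError):
            tag_density_per_kb(self.make_tags([]), [])


GENES = [
    GeneModel("g1", GenomicInterval("chr1", 10_000, 30_000, "+")),
    GeneModel("g2", GenomicInterval("chr1", 50_000, 70_000, "-")),
]


class TestClassifyLocation:
    def test_region_over_tss_is_promoter(self):
        assert classify_location(GenomicInterval("chr1", 9_800, 10_200), GENES) == "promoter"

    def test_minus_strand_tss_is_at_right_end(self):
        assert classify_location(GenomicInterval("chr1", 69_600, 70_300), GENES) == "promoter"

    def test_gene_body_far_from_tss_is_intragenic(self):
        assert classify_location(GenomicInterval("chr1", 15_000, 16_000), GENES) == "intragenic"

    def test_no_overlap_is_intergenic(self):
        assert classify_location(GenomicInterval("chr1", 40_000, 41_000), GENES) == "intergenic"

    def test_matches_brute_force_rule(self, rng):
        genes = []
        for i in range(50):
            start = int(rng.integers(0, 480_000))
            genes.append(
                GeneModel(
                    f"g{i}",
                    GenomicInterval(
                        "chr1", start, start + int(rng.integers(2_000, 20_000)),
                        "+" if rng.random() < 0.5 else "-",
                    ),
                )
            )
        hw = 500
        for region in random_intervals(rng, 500, extent=490_000):
            promoter = any(
                overlap(region, GenomicInterval(g.span.chrom, max(0, g.tss - hw), g.tss + hw)) > 0
                for g in genes
            )
            intragenic = any(overlap(region, g.span) > 0 for g in genes)
            expected = "promoter" if promoter else ("intragenic" if intragenic else "intergenic")
            assert classify_location(region, genes, hw) == expected


class TestNearestGene:
    def test_region_inside_gene(self):
        assert nearest_gene(GenomicInterval("chr1", 15_000, 16_000), GENES) == "g1"

    def test_tie_broken_by_tss_distance(self):
        # equidistant from g1 (end 30k) and g2 (start 50k): gaps 500 each;
        # g2's TSS (69,999) is farther than g1's (10,000)... both far; g1 wins on id
        region = GenomicInterval("chr1", 30_500, 49_500)
        assert nearest_gene(region, GENES) == "g1"

    def test_no_gene_on_chromosome(self):
        assert nearest_gene(GenomicInterval("chrX", 0, 100), GENES) == "none"

    def test_matches_exhaustive_search(self, rng):
        genes = []
        for i in range(80):
            start = int(rng.integers(0, 900_000))
            genes.append(
                GeneModel(
                    f"g{i:03d}",
                    GenomicInterval("chr1", start, start + int(rng.integers(1_000, 9_000)), "+"),
                )
            )
        for region in random_intervals(rng, 1000, extent=950_000):
            gaps = []
            for g in genes:
                gap = max(0, max(region.start, g.span.start) - min(region.end, g.span.end))
                tss_gap = max(0, region.start - g.tss, g.tss - (region.end - 1))
                gaps.append((gap, tss_gap, g.gene_id))
            assert nearest_gene(region, genes) == min(gaps)[2]


class TestMotifDensity:
    def brute_scores(self, seq, pwm):
        """Position-by-position scoring oracle on both strands."""
        comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
        idx = {"A": 0, "C": 1, "G": 2, "T": 3}
        hits = []
        for strand in ("+", "-"):
            s = seq if strand == "+" else "".join(comp[c] for c in reversed(seq))
            for i in range(len(s) - len(pwm) + 1):
                window = s[i : i + len(pwm)]
                if "N" in window:
                    continue
                score = sum(pwm.matrix[j, idx[c]] for j, c in enumerate(window))
                if score >= pwm.score_threshold - 1e-12:
                    offset = i if strand == "+" else len(s) - len(pwm) - i
                    hits.append((offset, strand))
        return sorted(hits)

    def test_zero_hits_zero_density(self):
        pwm = Pwm.from_consensus("gc", "GGGGCGGG", threshold_fraction=0.99)
        region = GenomicInterval("chr1", 0, 40)
        density = motif_density([(region, "AT" * 20)], [pwm])
        assert density["gc"] == 0.0

    def test_planted_consensus_found(self):
        pwm = Pwm.from_consensus("creb", "TGACGTCA", threshold_fraction=1.0)
        seq = "A" * 500 + "TGACGTCA" + "A" * 492
        region = GenomicInterval("chr1", 0, 1000)
        density = motif_density([(region, seq)], [pwm])
        assert density["creb"] >= 1.0  # palindromic: reverse strand hits too

    def test_n_windows_skipped(self):
        pwm = Pwm.from_consensus("m", "ACGT", threshold_fraction=1.0)
        assert motif_density([(GenomicInterval("chr1", 0, 8), "ACNTACGT")], [pwm])["m"] > 0

    def test_length_mismatch_rejected(self):
        pwm = Pwm.from_consensus("m", "ACGT")
        with pytest.raises(ValueError, match="length"):
            motif_density([(GenomicInterval("chr1", 0, 10), "ACGT")], [pwm])

    def test_matches_position_by_position_oracle(self, rng):
        bases = np.array(list("ACGT"))
        seq = "".join(rng.choice(bases, size=20_000))
        seq = seq[:5000] + "N" + seq[5001:]
        consensi = ["CCAAT", "TGACGTCA", "GGGGCGGG", "CCGCCC", "TATAAA", "GCGCATGCGC"]
        for consensus in consensi:
            pwm = Pwm.from_consensus(f"m_{consensus}", consensus, threshold_fraction=0.85)
            assert scan_pwm(seq, pwm) == self.brute_scores(seq, pwm)


class TestRepeatFraction:
    def test_no_overlap_zero_percent(self):
        result = repeat_fraction_histogram(
            [GenomicInterval("chr1", 0, 1000)], [GenomicInterval("chr1", 5000, 6000)]
        )
        assert result.percents == [0.0]
        assert result.decile_counts[0] == 1

    def test_overlapping_repeats_counted_once(self):
        peak = GenomicInterval("chr1", 0, 1000)
        repeats = [
            GenomicInterval("chr1", 0, 600),
            GenomicInterval("chr1", 400, 950),  # overlaps the first
        ]
        result = repeat_fraction_histogram([peak], repeats)
        assert result.percents == [95.0]
        assert result.top_decile_count() == 1

    def test_matches_per_bp_membership_oracle(self, rng):
        peaks = random_intervals(rng, 200, extent=100_000, max_len=1_500)
        repeats = random_intervals(rng, 300, extent=100_000, max_len=800)
        covered = np.zeros(100_000, dtype=bool)
        for r in repeats:
            covered[r.start : r.end] = True
        result = repeat_fraction_histogram(peaks, repeats)
        for peak, pct in zip(peaks, result.percents):
            oracle = 100.0 * covered[peak.start : peak.end].mean()
            assert pct == pytest.approx(oracle)
        assert all(0 <= p <= 100 for p in result.percents)

    def test_top_decile_ratio(self):
        a = repeat_fraction_histogram(
            [GenomicInterval("chr1", 0, 100)] * 1, [GenomicInterval("chr1", 0, 100)]
        )
        with pytest.raises(ZeroDivisionError):
            top_decile_ratio(a, repeat_fraction_histogram([GenomicInterval("chr1", 0, 10)], []))
        assert top_decile_ratio(a, a) == 1.0


class TestFingerDomainAssociation:
    def genes_with_fingers(self, counts):
        genes = []
        for i, k in enumerate(counts):
            start = i * 10_000
            genes.append(
                GeneModel(
                    f"g{i}", GenomicInterval("chr1", start, start + 5_000, "+"),
                    n_finger_domains=k,
                )
            )
        return genes

    def test_no_peaks_all_zero(self):
        genes = self.genes_with_fingers([1, 1, 5, 5])
        out = finger_domain_association(genes, [])
        assert out == {1: 0.0, 5: 0.0}

    def test_full_coverage_all_hundred(self):
        genes = self.genes_with_fingers([2, 3])
        peaks = [g.span for g in genes]
        assert finger_domain_association(genes, peaks) == {2: 100.0, 3: 100.0}

    def test_empty_classes_absent_not_zero(self):
        genes = self.genes_with_fingers([4, 4])
        out = finger_domain_association(genes, [])
        assert 5 not in out and 4 in out

    def test_unannotated_genes_rejected(self):
        genes = [GeneModel("g", GenomicInterval("chr1", 0, 100, "+"))]
        with pytest.raises(ValueError, match="finger"):
            finger_domain_association(genes, [])


class TestSummaryStats:
    def test_mean_max_height(self):
        mk = lambda h: PeakRegion(GenomicInterval("chr1", 0, 100), h, h * 100, h)
        assert mean_max_height([mk(7)]) == 7
        assert mean_max_height([mk(2), mk(4)]) == 3
        with pytest.raises(ValueError):
            mean_max_height([])

    def test_mean_matches_oracle_on_simulated_regions(self, rng):
        heights = rng.uniform(1, 50, size=200)
        regions = [
            PeakRegion(GenomicInterval("chr1", i * 200, i * 200 + 100), h, h * 100, h)
            for i, h in enumerate(heights)
        ]
        assert mean_max_height(regions) == pytest.approx(float(heights.mean()))

    @pytest.mark.parametrize(
        "a,b,expected",
        [
            (3_416_942, 14_139_035, 4.1),
            (9_672_419, 65_057_655, 6.7),
            (9_212_672, 35_215_276, 3.8),
            (7.0, 7.0, 1.0),
        ],
    )
    def test_fold_coverage_difference(self, a, b, expected):
        assert fold_coverage_difference(a, b) == expected

    def test_fold_zero_coverage_rejected(self):
        with pytest.raises(ValueError):
            fold_coverage_difference(0, 10)
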