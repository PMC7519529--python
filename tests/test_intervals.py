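"""Reproducible-peak rule, region merging, and peak-to-gene assignment."""
import numpy as np
import pytest

from chromkit.core import Gene, GenomeAnnotation, Peak
from chromkit.intervals import (AssignmentConfig, SingleReplicateError,
                                assign_bound_genes, assign_distal_elements,
                                classify_feature_overlap,
                                finalize_reproducible_peaks, merge_reference_regions)
from chromkit.simulate import simulate_peak_replicates


def P(start, end, q=0.01, chrom="chr1", sample=""):
    return Peak(chrom, start, end, q_value=q, sample_id=sample)


class TestFinalize:
    def test_stringent_with_lenient_partner_is_retained(self):
        final = finalize_reproducible_peaks([[P(100, 300, q=0.01)], [P(250, 500, q=0.3)]])
        assert [(p.start, p.end) for p in final] == [(100, 300)]

    def test_stringent_without_partner_is_dropped(self):
        final = finalize_reproducible_peaks([[P(100, 300, q=0.01)], [P(800, 900, q=0.3)]])
        assert final == []

    def test_partner_above_lenient_cutoff_does_not_support(self):
        final = finalize_reproducible_peaks([[P(100, 300, q=0.01)], [P(250, 500, q=0.6)]])
        assert final == []

    def test_survivors_from_both_replicates_merge_to_union(self):
        final = finalize_reproducible_peaks(
            [[P(100, 300, q=0.01)], [P(250, 500, q=0.02)]])
        assert [(p.start, p.end) for p in final] == [(100, 500)]

    def test_single_replicate_is_an_error(self):
        with pytest.raises(SingleReplicateError, match="skip finalization"):
            finalize_reproducible_peaks([[P(1, 2)]])

    def test_three_replicates_require_lenient_support_in_all_others(self):
        reps = [[P(100, 300, q=0.01)], [P(150, 350, q=0.3)], [P(800, 900, q=0.3)]]
        assert finalize_reproducible_peaks(reps) == []
        reps[2] = [P(120, 320, q=0.45)]
        assert [(p.start, p.end) for p in finalize_reproducible_peaks(reps)] == [(100, 300)]

    @pytest.mark.parametrize("fraction", [0.0, 0.6, 1.0])
    def test_simulated_truth_recovered_exactly(self, annotation, fraction):
        rep1, rep2, truth = simulate_peak_replicates(
            annotation, n_true=100, reproducible_fraction=fraction, seed=11)
        final = finalize_reproducible_peaks([rep1, rep2])
        expected = truth[truth["reproducible"]]
        assert {(p.chrom, p.start, p.end) for p in final} == \
               {(r.chrom, r.start, r.end) for r in expected.itertuples()}

    def test_relaxing_q_weak_never_removes_a_survivor(self, annotation):
        rep1, rep2, _ = simulate_peak_replicates(annotation, n_true=80,
                                                 reproducible_fraction=0.5, seed=13)
        tight = {(p.chrom, p.start, p.end)
                 for p in finalize_reproducible_peaks([rep1, rep2], q_weak=0.2)}
        loose = {(p.chrom, p.start, p.end)
                 for p in finalize_reproducible_peaks([rep1, rep2], q_weak=0.5)}
        assert tight <= loose

    def test_survivors_subset_of_stringent_union(self, annotation):
        rep1, rep2, _ = simulate_peak_replicates(annotation, n_true=80,
                                                 reproducible_fraction=0.5, seed=17)
        final = finalize_reproducible_peaks([rep1, rep2])
        stringent = merge_reference_regions(
            [[p for p in rep1 + rep2 if p.q_value <= 0.05]])
        covered = {(f.chrom, f.start, f.end) for f in final} <= \
                  {(s.chrom, s.start, s.end) for s in stringent}
        assert covered


class TestMerge:
    def test_overlapping_intervals_union(self):
        merged = merge_reference_regions([[P(100, 200)], [P(150, 250)]])
        assert [(p.start, p.end) for p in merged] == [(100, 250)]

    def test_disjoint_sets_concatenate_sorted(self):
        merged = merge_reference_regions([[P(500, 600)], [P(100, 200)]])
        assert [(p.start, p.end) for p in merged] == [(100, 200), (500, 600)]
        assert len(merged) == 2

    def test_idempotent_and_order_invariant(self):
        rng = np.random.default_rng(0)
        sets = [[P(int(s), int(s) + int(l))
                 for s, l in zip(rng.integers(0, 99_000, 300), rng.integers(1, 800, 300))]
                for _ in range(3)]
        once = merge_reference_regions(sets)
        assert merge_reference_regions([once]) == once
        reordered = merge_reference_regions(sets[::-1])
        assert [(p.start, p.end) for p in reordered] == [(p.start, p.end) for p in once]

    def test_matches_per_base_occupancy_oracle(self):
        rng = np.random.default_rng(42)
        peaks = [P(int(s), int(s) + int(l))
                 for s, l in zip(rng.integers(0, 99_000, 1000), rng.integers(1, 500, 1000))]
        merged = merge_reference_regions([peaks])
        mask = np.zeros(100_000, dtype=bool)
        for p in peaks:
            mask[p.start:p.end] = True
        # reconstruct intervals from the occupancy mask
        padded = np.concatenate(([False], mask, [False]))
        diff = np.diff(padded.astype(np.int8))
        oracle = list(zip(np.nonzero(diff == 1)[0], np.nonzero(diff == -1)[0]))
        assert [(p.start, p.end) for p in merged] == [(int(a), int(b)) for a, b in oracle]


@pytest.fixture
def two_gene_annotation():
    return GenomeAnnotation(
        {"chr1": 1_000_000},
        [Gene("gplus", "chr1", 5000, 8000, "+"),     # TSS 5000
         Gene("gminus", "chr1", 2000, 5001, "-")])   # TSS 5000 (end-1)


class TestAssignment:
    def test_promoter_window_arithmetic_plus_strand(self, two_gene_annotation):
        bound = assign_bound_genes([P(6500, 6600)], two_gene_annotation)
        assert "gplus" in bound  # window [3000, 7000)

    def test_minus_strand_tss_is_gene_end(self, two_gene_annotation):
        bound = assign_bound_genes([P(6500, 6600)], two_gene_annotation)
        assert "gminus" in bound

    def test_peak_outside_all_windows(self, two_gene_annotation):
        assert assign_bound_genes([P(7100, 7200)], two_gene_annotation) == set()

    def test_unknown_chromosome_skipped_with_warning(self, two_gene_annotation, caplog):
        with caplog.at_level("WARNING"):
            bound = assign_bound_genes([P(6500, 6600, chrom="chrUn")], two_gene_annotation)
        assert bound == set()
        assert "skipped 1" in caplog.text

    def test_planted_promoter_peaks_recover_exact_gene_set(self, annotation):
        rng = np.random.default_rng(3)
        chosen = rng.choice(len(annotation.genes), size=20, replace=False)
        targets = {annotation.genes[i].gene_id for i in chosen}
        peaks = [Peak(annotation.genes[i].chrom, annotation.genes[i].tss - 25,
                      annotation.genes[i].tss + 25, q_value=0.01) for i in chosen]
        assert assign_bound_genes(peaks, annotation) == targets

    def test_invariant_to_order_and_abutting_split(self, annotation):
        g = annotation.genes[5]
        whole = [Peak(g.chrom, g.tss - 100, g.tss + 100)]
        split = [Peak(g.chrom, g.tss, g.tss + 100), Peak(g.chrom, g.tss - 100, g.tss)]
        assert assign_bound_genes(whole, annotation) == assign_bound_genes(split, annotation)
        assert assign_bound_genes(split[::-1], annotation) == \
               assign_bound_genes(split, annotation)

    def test_distal_window_membership(self, two_gene_annotation):
        region = P(10_000, 10_100)
        mapping = assign_distal_elements([region], two_gene_annotation)
        assert "gplus" in mapping[region]  # 5000 bp from TSS, outside promoter

    def test_region_inside_promoter_excluded_from_distal(self, two_gene_annotation):
        region = P(6000, 6100)
        mapping = assign_distal_elements([region], two_gene_annotation)
        assert mapping[region] == set()

    def test_promoter_and_distal_disjoint_per_gene(self, annotation):
        rng = np.random.default_rng(7)
        regions = [Peak("chrS1", int(s), int(s) + 200)
                   for s in rng.integers(0, 399_000, 200)]
        cfg = AssignmentConfig()
        distal = assign_distal_elements(regions, annotation, cfg)
        for region, gene_ids in distal.items():
            promoter_hits = assign_bound_genes([region], annotation, cfg)
            assert not (gene_ids & promoter_hits)

    def test_distal_matches_bruteforce_pairwise_oracle(self, annotation):
        rng = np.random.default_rng(19)
        regions = [Peak("chrS1", int(s), int(s) + int(l))
                   for s, l in zip(rng.integers(0, 398_000, 150),
                                   rng.integers(50, 1500, 150))]
        cfg = AssignmentConfig()
        got = assign_distal_elements(regions, annotation, cfg)
        for region in regions:
            expected = set()
            for g in annotation.genes:
                tss = g.tss
                if tss < region.start:
                    d = region.start - tss
                elif tss >= region.end:
                    d = tss - (region.end - 1)
                else:
                    d = 0
                plo, phi = max(0, tss - 2000), tss + 2000
                overlaps_promoter = region.start < phi and plo < region.end
                if 2000 <= d <= 50_000 and not overlaps_promoter:
                    expected.add(g.gene_id)
            assert got[region] == expected


class TestFeatureOverlap:
    def test_flags_and_summary(self):
        regions = [P(0, 100), P(200, 300), P(400, 500)]
        features = {"H3K27ac": [P(50, 150)], "ATAC": [P(250, 260)]}
        records, summary, tables = classify_feature_overlap(regions, features)
        assert records[0].flags == {"H3K27ac": True, "ATAC": False}
        assert records[1].flags == {"H3K27ac": False, "ATAC": True}
        assert summary == {"n_regions": 3, "n_with_any": 2, "n_with_none": 1}
        table = tables[("H3K27ac", "ATAC")]
        assert table.sum() == 3 and table[0, 1] == 1 and table[1, 0] == 1

    def test_no_overlap_anywhere(self):
        _, summary, _ = classify_feature_overlap([P(0, 10), P(20, 30)],
                                                 {"f": [P(1000, 1100)]})
        assert summary["n_with_none"] == 2

    def test_planted_split_matches_construction(self):
        regions = [P(i * 1000, i * 1000 + 100) for i in range(100)]
        feature = [P(i * 1000, i * 1000 + 50) for i in range(70)]  # first 70 overlap
        _, summary, _ = classify_feature_overlap(regions, {"mark": feature})
        assert summary["n_with_any"] == 70
        assert summary["n_with_none"] == 30

    def test_requires_a_feature_set(self):
        with pytest.raises(ValueError):
            classify_feature_overlap([P(0, 10)], {})
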