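"""CRISPR off-target screen: site scan, indel calling, deletion and insertion detection."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from chromkit.core import AlignmentRecord
from chromkit.offtarget import (GuideSpec, _revcomp, call_small_indels,
                                cross_sample_validate, deletion_scan,
                                insertion_breakpoints, predict_offtarget_sites,
                                run_screen, softclip_breakpoints)
from chromkit.simulate import (PlantedEdit, SimulationConfig, _random_sequence,
                               plant_protospacer_sites, simulate_wgs_alignments)

GUIDE = "TATGAGTCTAGTTTAAAGGT"


def naive_site_scan(reference, guide: GuideSpec):
    """Independent per-window re-scan (oracle for the vectorized scanner)."""
    from chromkit.offtarget import _IUPAC
    hits = set()
    glen = len(guide.protospacer)
    for chrom, seq in reference.items():
        seq = seq.upper()
        L = len(seq)
        for strand, s in (("+", seq), ("-", _revcomp(seq))):
            for i in range(L - glen - len(guide.pam) + 1):
                mm = sum(1 for a, b in zip(s[i:i + glen], guide.protospacer)
                         if a != b or a not in "ACGT")
                if mm > guide.max_mismatches:
                    continue
                pam = s[i + glen:i + glen + len(guide.pam)]
                if all(p in _IUPAC[q] for p, q in zip(pam, guide.pam)):
                    start = i if strand == "+" else L - i - glen
                    hits.add((chrom, start, strand, mm))
    return hits


class TestSiteScan:
    def test_planted_exact_site_on_minus_strand(self):
        rng = np.random.default_rng(0)
        seq = _random_sequence(rng, 2000)
        payload = _revcomp(GUIDE + "AGG")
        seq = seq[:1000] + payload + seq[1000 + len(payload):]
        sites = predict_offtarget_sites({"c": seq}, GuideSpec(GUIDE))
        hit = sites[(sites.start == 1003) & (sites.strand == "-")]
        assert len(hit) == 1 and hit.n_mismatches.iloc[0] == 0

    def test_five_mismatches_absent(self):
        rng = np.random.default_rng(1)
        seq = _random_sequence(rng, 2000)
        proto = list(GUIDE)
        for p in (0, 4, 8, 12, 16):
            proto[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[proto[p]]
        payload = "".join(proto) + "AGG"
        seq = seq[:500] + payload + seq[500 + len(payload):]
        sites = predict_offtarget_sites({"c": seq}, GuideSpec(GUIDE, max_mismatches=4))
        assert not ((sites.start == 500) & (sites.strand == "+")).any()

    def test_pam_is_required(self):
        seq = "T" * 50 + GUIDE + "ATT" + "T" * 50  # ATT fails NGG
        sites = predict_offtarget_sites({"c": seq}, GuideSpec(GUIDE))
        assert not ((sites.start == 50) & (sites.strand == "+")).any()

    def test_matches_independent_naive_scan(self):
        rng = np.random.default_rng(2)
        seq, _ = plant_protospacer_sites(_random_sequence(rng, 100_000), GUIDE,
                                         n_sites=12, seed=3)
        guide = GuideSpec(GUIDE)
        got = {(r.chrom, r.start, r.strand, r.n_mismatches)
               for r in predict_offtarget_sites({"c": seq}, guide).itertuples()}
        assert got == naive_site_scan({"c": seq}, guide)

    def test_guide_validation(self):
        with pytest.raises(ValueError):
            GuideSpec("ACGT")  # not 20 nt


def read(pos, cigar, sample="KO", chrom="c"):
    return AlignmentRecord(chrom, pos, cigar, sample_id=sample)


class TestIndels:
    def test_planted_half_fraction_deletion_called(self):
        sizes = {"chrS1": 100_000}
        edit = PlantedEdit("small_indel", "chrS1", 50_000, 3, allele_fraction=0.5)
        cfg = SimulationConfig(seed=6, planted_edits=(edit,))
        aligns, _ = simulate_wgs_alignments(sizes, cfg, depth=30)
        calls = call_small_indels(aligns["KO"], sizes, sample_id="KO")
        (call,) = [c for c in calls if c.ref_len == 3]
        assert call.pos == 50_000
        assert 0.35 <= call.alt_fraction <= 0.65

    def test_fraction_below_threshold_not_called(self):
        sizes = {"chrS1": 100_000}
        edit = PlantedEdit("small_indel", "chrS1", 50_000, 3, allele_fraction=0.03)
        cfg = SimulationConfig(seed=6, planted_edits=(edit,))
        aligns, _ = simulate_wgs_alignments(sizes, cfg, depth=30)
        assert call_small_indels(aligns["KO"], sizes) == []

    def test_coverage_below_threshold_not_called(self):
        sizes = {"c": 1000}
        reads = [read(100, (("M", 50), ("D", 2), ("M", 50)))] * 2
        assert call_small_indels(reads, sizes, min_coverage=5) == []

    def test_insertion_op_called_with_position(self):
        sizes = {"c": 1000}
        reads = [read(100, (("M", 50), ("I", 4), ("M", 46))) for _ in range(6)]
        (call,) = call_small_indels(reads, sizes)
        assert (call.pos, call.ref_len, call.alt_len) == (150, 0, 4)
        assert call.alt_fraction == 1.0


class TestCrossValidation:
    sites = pd.DataFrame({"chrom": ["c", "c"], "start": [10_000, 40_000],
                          "strand": ["+", "-"], "n_mismatches": [0, 3]})

    def _call(self, pos, sample):
        from chromkit.offtarget import IndelCall
        return IndelCall("c", pos, 3, 0, 30, 0.5, sample)

    def test_edited_only_near_predicted_site_is_candidate(self):
        part = cross_sample_validate({"KO": [self._call(40_002, "KO")], "WT": []},
                                     ["KO"], ["WT"], self.sites)
        assert [c.pos for c in part["candidate_offtarget"]] == [40_002]

    def test_shared_with_control_is_artifact(self):
        calls = {"KO": [self._call(40_002, "KO")], "WT": [self._call(40_002, "WT")]}
        part = cross_sample_validate(calls, ["KO"], ["WT"], self.sites)
        assert [c.pos for c in part["artifact"]] == [40_002]

    def test_on_target_locus_classified_first(self):
        part = cross_sample_validate({"KO": [self._call(10_005, "KO")], "WT": []},
                                     ["KO"], ["WT"], self.sites)
        assert [c.pos for c in part["on_target"]] == [10_005]

    def test_far_from_any_site_goes_to_review_not_dropped(self):
        part = cross_sample_validate({"KO": [self._call(90_000, "KO")], "WT": []},
                                     ["KO"], ["WT"], self.sites)
        assert [c.pos for c in part["review"]] == [90_000]

    def test_partition_is_exhaustive_and_disjoint(self):
        calls = {"KO": [self._call(p, "KO") for p in (10_005, 40_002, 90_000, 55_000)],
                 "WT": [self._call(55_000, "WT")]}
        part = cross_sample_validate(calls, ["KO"], ["WT"], self.sites)
        classified = [c.pos for lst in part.values() for c in lst]
        assert sorted(classified) == [10_005, 40_002, 55_000, 90_000]

    def test_empty_control_group_is_error(self):
        with pytest.raises(ValueError, match="control"):
            cross_sample_validate({"KO": []}, ["KO"], [], self.sites)


class TestDeletionScan:
    def _cov(self, depth, n=20_000):
        return np.full(n, depth, dtype=np.int32)

    def test_uniform_coverage_flags_nothing(self):
        cov = {"KO": {"c": self._cov(30)}, "WT": {"c": self._cov(30)}}
        assert deletion_scan(cov, ["KO"], ["WT"]).empty

    def test_identical_arrays_null_self_consistency(self):
        rng = np.random.default_rng(0)
        arr = rng.poisson(30, 20_000).astype(np.int32)
        cov = {"KO": {"c": arr}, "WT": {"c": arr.copy()}}
        assert deletion_scan(cov, ["KO"], ["WT"]).empty

    def test_zero_span_flagged_with_poisson_tail(self):
        ko = self._cov(30)
        ko[5_000:5_200] = 0
        cov = {"KO": {"c": ko}, "WT": {"c": self._cov(30)}}
        result = deletion_scan(cov, ["KO"], ["WT"])
        assert len(result) == 1
        row = result.iloc[0]
        assert row.start <= 5_000 and row.end >= 5_200
        # per-position p over the span is the closed-form Poisson(30) lower tail at 0
        assert row.mean_p <= stats.poisson.cdf(0, 30) * 1.01

    def test_short_dip_not_flagged(self):
        ko = self._cov(30)
        ko[5_000:5_040] = 0  # 40 bp <= 50
        cov = {"KO": {"c": ko}, "WT": {"c": self._cov(30)}}
        assert deletion_scan(cov, ["KO"], ["WT"]).empty

    def test_region_also_low_in_control_removed(self):
        ko = self._cov(30)
        wt = self._cov(30)
        ko[5_000:5_200] = 0
        wt[5_000:5_200] = 0
        lam_source = self._cov(30)
        cov = {"KO": {"c": ko}, "WT": {"c": wt}, "WT2": {"c": lam_source}}
        result = deletion_scan(cov, ["KO"], ["WT", "WT2"])
        # control WT is just as improbable over the span -> cross-filtered out
        assert result.empty

    def test_zero_control_genome_cannot_calibrate(self):
        cov = {"KO": {"c": self._cov(30)}, "WT": {"c": self._cov(0)}}
        with pytest.raises(ValueError, match="calibrate"):
            deletion_scan(cov, ["KO"], ["WT"])


class TestInsertions:
    def _clipped(self, sample, pos, direction, clip=20):
        if direction == "right":
            return read(pos - 80, (("M", 80), ("S", clip)), sample=sample)
        return read(pos, (("S", clip), ("M", 80)), sample=sample)

    def test_paired_bidirectional_breakpoints_within_window(self):
        aligns = {"KO": [self._clipped("KO", 5_000, "right"),
                         self._clipped("KO", 5_003, "left")],
                  "WT": []}
        result = insertion_breakpoints(aligns, ["KO"], ["WT"])
        assert [(r.left, r.right) for r in result.itertuples()] == [(5_000, 5_003)]

    def test_clusters_eight_apart_not_paired(self):
        aligns = {"KO": [self._clipped("KO", 5_000, "right"),
                         self._clipped("KO", 5_008, "left")],
                  "WT": []}
        assert insertion_breakpoints(aligns, ["KO"], ["WT"]).empty

    def test_overhang_of_exactly_ten_excluded(self):
        points = softclip_breakpoints([read(0, (("M", 80), ("S", 10)))], min_overhang=10)
        assert points == []
        points = softclip_breakpoints([read(0, (("M", 80), ("S", 11)))], min_overhang=10)
        assert points == [("c", 80, "right_clip")]

    def test_control_breakpoints_cross_filtered(self):
        aligns = {"KO": [self._clipped("KO", 5_000, "right"),
                         self._clipped("KO", 5_002, "left")],
                  "WT": [self._clipped("WT", 5_001, "right")]}
        assert insertion_breakpoints(aligns, ["KO"], ["WT"]).empty


class TestFullScreen:
    def test_clean_genome_yields_no_offtarget_candidates(self):
        rng = np.random.default_rng(10)
        seq = _random_sequence(rng, 120_000)
        seq = seq[:60_000] + GUIDE + "AGG" + seq[60_023:]
        cfg = SimulationConfig(seed=10)
        aligns, _ = simulate_wgs_alignments({"c": len(seq)}, cfg, depth=20,
                                            sequences={"c": seq})
        result = run_screen({"c": seq}, aligns, GuideSpec(GUIDE), ["KO"], ["WT"])
        assert result.indel_partition["candidate_offtarget"] == []
        assert result.indel_partition["review"] == []
        assert result.deletions.empty
        assert result.insertions.empty

    def test_planted_events_recovered(self):
        rng = np.random.default_rng(11)
        seq = _random_sequence(rng, 200_000)
        seq = seq[:60_000] + GUIDE + "AGG" + seq[60_023:]
        edits = (PlantedEdit("small_indel", "c", 60_010, 3, allele_fraction=0.5),
                 PlantedEdit("long_deletion", "c", 120_000, 200),
                 PlantedEdit("insertion", "c", 160_000, 400, allele_fraction=0.8))
        cfg = SimulationConfig(seed=12, planted_edits=edits)
        aligns, _ = simulate_wgs_alignments({"c": len(seq)}, cfg, depth=30,
                                            sequences={"c": seq})
        result = run_screen({"c": seq}, aligns, GuideSpec(GUIDE), ["KO"], ["WT"])
        assert [c.pos for c in result.indel_partition["on_target"]] == [60_010]
        assert result.indel_partition["candidate_offtarget"] == []
        (deletion,) = result.deletions.itertuples()
        assert deletion.start <= 120_000 and deletion.end >= 120_200
        assert len(result.insertions) == 1
        ins = result.insertions.iloc[0]
        assert ins.left == 160_000 and ins.right == 160_000
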