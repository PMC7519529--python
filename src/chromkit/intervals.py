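"""Interval algebra, reproducible-peak finalization, and peak-to-gene maps.

Peak replicability follows the two-threshold rule used for ChIP/ATAC peak
sets: a site is kept when it is called at a stringent significance cutoff
(q <= q_strong, default 0.05) in one replicate and at least at a relaxed
cutoff (q <= q_weak, default 0.5) in every other replicate. Promoters are
symmetric +/-2 kb windows around the TSS; distal elements lie 2-50 kb from
the TSS and outside the promoter window.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree

from .core import GenomeAnnotation, Peak, sort_peaks

logger = logging.getLogger(__name__)


@dataclass
class AssignmentConfig:
    promoter_halfwidth: int = 2000
    distal_min: int = 2000
    distal_max: int = 50000
    distal_anchor: str = "tss"  # 'tss' or 'gene_edge'

    def __post_init__(self) -> None:
        if not 0 < self.distal_min < self.distal_max:
            raise ValueError("require 0 < distal_min < distal_max")
        if self.distal_anchor not in ("tss", "gene_edge"):
            raise ValueError("distal_anchor must be 'tss' or 'gene_edge'")


@dataclass
class FeatureOverlapRecord:
    region: Peak
    flags: dict[str, bool]


class SingleReplicateError(ValueError):
    """Raised when finalization is requested with fewer than two replicates."""


def _tree_by_chrom(peaks: Sequence[Peak]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for p in peaks:
        trees.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end, p)
    return trees


def finalize_reproducible_peaks(
    replicate_calls: Sequence[Sequence[Peak]],
    q_strong: float = 0.05,
    q_weak: float = 0.5,
) -> list[Peak]:
    """Keep stringent peaks supported leniently in every other replicate.

    `replicate_calls` holds, per replicate, the full call set at the lenient
    threshold (q-values attached); the stringent subset is q <= q_strong.
    A stringent peak from any replicate survives iff it overlaps (>= 1 bp) a
    call with q <= q_weak in every other replicate. Overlapping survivors
    from different replicates are merged into their union interval; output
    sorted by (chrom, start).
    """
    if q_strong > q_weak:
        raise ValueError("q_strong must be <= q_weak")
    if len(replicate_calls) < 2:
        raise SingleReplicateError(
            "finalization needs >= 2 replicates; with a single replicate, skip "
            "finalization explicitly and use its calls directly")
    lenient_trees = [_tree_by_chrom([p for p in calls if p.q_value <= q_weak])
                     for calls in replicate_calls]
    survivors: list[Peak] = []
    for r, calls in enumerate(replicate_calls):
        for p in calls:
            if p.q_value > q_strong:
                continue
            supported = all(
                lenient_trees[s].get(p.chrom, IntervalTree()).overlaps(p.start, p.end)
                for s in range(len(replicate_calls)) if s != r
            )
            if supported:
                survivors.append(p)
    return merge_reference_regions([survivors])


def merge_reference_regions(peak_sets: Sequence[Sequence[Peak]]) -> list[Peak]:
    """Union of all intervals; overlapping or bookended intervals are merged."""
    peaks = sort_peaks([p for ps in peak_sets for p in ps])
    merged: list[Peak] = []
    for p in peaks:
        if merged and merged[-1].chrom == p.chrom and p.start <= merged[-1].end:
            last = merged[-1]
            if p.end > last.end:
                merged[-1] = Peak(last.chrom, last.start, p.end,
                                  score=max(last.score, p.score),
                                  q_value=min(last.q_value, p.q_value))
        else:
            merged.append(Peak(p.chrom, p.start, p.end, score=p.score, q_value=p.q_value))
    return merged


def promoter_window(tss: int, halfwidth: int, chrom_size: int | None = None) -> tuple[int, int]:
    lo = max(0, tss - halfwidth)
    hi = tss + halfwidth
    if chrom_size is not None:
        hi = min(hi, chrom_size)
    return lo, hi


def assign_bound_genes(
    peaks: Sequence[Peak],
    annotation: GenomeAnnotation,
    cfg: AssignmentConfig | None = None,
) -> set[str]:
    """Genes whose +/-halfwidth TSS window intersects >= 1 peak.

    Peaks on chromosomes absent from the annotation are skipped with a
    logged warning count; a peak may bind multiple genes.
    """
    cfg = cfg or AssignmentConfig()
    known = set(annotation.chrom_sizes)
    skipped = sum(1 for p in peaks if p.chrom not in known)
    if skipped:
        logger.warning("assign_bound_genes: skipped %d peaks on unknown chromosomes", skipped)
    trees = _tree_by_chrom([p for p in peaks if p.chrom in known])
    bound: set[str] = set()
    for g in annotation.genes:
        lo, hi = promoter_window(g.tss, cfg.promoter_halfwidth, annotation.chrom_sizes[g.chrom])
        if lo < hi and trees.get(g.chrom, IntervalTree()).overlaps(lo, hi):
            bound.add(g.gene_id)
    return bound


def _region_tss_distance(start: int, end: int, tss: int) -> int:
    """Bases between the closest points of [start,end) and the TSS base; 0 if inside."""
    if tss < start:
        return start - tss
    if tss >= end:
        return tss - (end - 1)
    return 0


def assign_distal_elements(
    regions: Sequence[Peak],
    annotation: GenomeAnnotation,
    cfg: AssignmentConfig | None = None,
) -> dict[Peak, set[str]]:
    """Map region -> genes whose TSS lies distal_min..distal_max away.

    A region is distal to a gene iff its closest-point distance to the TSS
    lies in [distal_min, distal_max] and the region does not intersect the
    promoter window (so promoter and distal assignments are disjoint).
    """
    cfg = cfg or AssignmentConfig()
    known = set(annotation.chrom_sizes)
    skipped = sum(1 for p in regions if p.chrom not in known)
    if skipped:
        logger.warning("assign_distal_elements: skipped %d regions on unknown chromosomes", skipped)
    genes_by_chrom = annotation.genes_by_chrom()
    out: dict[Peak, set[str]] = {}
    for region in regions:
        if region.chrom not in known:
            continue
        hits: set[str] = set()
        for g in genes_by_chrom.get(region.chrom, []):
            anchor = g.tss if cfg.distal_anchor == "tss" else None
            if anchor is None:  # gene_edge: closest gene-body point
                d = _interval_gap(region.start, region.end, g.start, g.end)
            else:
                d = _region_tss_distance(region.start, region.end, anchor)
            plo, phi = promoter_window(g.tss, cfg.promoter_halfwidth,
                                       annotation.chrom_sizes[g.chrom])
            intersects_promoter = region.start < phi and plo < region.end
            if cfg.distal_min <= d <= cfg.distal_max and not intersects_promoter:
                hits.add(g.gene_id)
        out[region] = hits
    return out


def _interval_gap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    if a_end <= b_start:
        return b_start - a_end + 1
    if b_end <= a_start:
        return a_start - b_end + 1
    return 0


def classify_feature_overlap(
    regions: Sequence[Peak],
    feature_sets: Mapping[str, Sequence[Peak]],
) -> tuple[list[FeatureOverlapRecord], dict[str, int], dict[tuple[str, str], np.ndarray]]:
    """Per-region presence flags for each named feature set.

    Returns (records, summary, pairwise contingency tables). The summary
    counts regions overlapping at least one feature (n_with_any) and none
    (n_with_none); each 2x2 table cross-tabulates presence of a feature pair
    across regions for downstream exact testing.
    """
    if not feature_sets:
        raise ValueError("need at least one feature set")
    trees = {name: _tree_by_chrom(ps) for name, ps in feature_sets.items()}
    records: list[FeatureOverlapRecord] = []
    for region in regions:
        flags = {
            name: trees[name].get(region.chrom, IntervalTree()).overlaps(region.start, region.end)
            for name in feature_sets
        }
        records.append(FeatureOverlapRecord(region, flags))
    n_any = sum(1 for r in records if any(r.flags.values()))
    summary = {"n_regions": len(records), "n_with_any": n_any,
               "n_with_none": len(records) - n_any}
    names = list(feature_sets)
    tables: dict[tuple[str, str], np.ndarray] = {}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            t = np.zeros((2, 2), dtype=np.int64)
            for r in records:
                t[0 if r.flags[a] else 1, 0 if r.flags[b] else 1] += 1
            tables[(a, b)] = t
    return records, summary, tables
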