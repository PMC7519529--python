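"""Spike-in-normalized signal quantification at promoters.

CUT&RUN libraries carry an exogenous (Drosophila) chromatin spike-in; since
the spike-in amount is constant across samples, each sample's signal is
rescaled by reference_constant / spike-in read count, making promoter
signal comparable between samples regardless of capture efficiency or
sequencing depth. Promoter signal is the count of target-species fragments
overlapping the +/-2 kb TSS window, times the sample's scale factor.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .core import FragmentRecord, GenomeAnnotation
from .intervals import promoter_window

logger = logging.getLogger(__name__)

DEFAULT_REFERENCE_CONSTANT = 10_000.0


@dataclass
class SignalMatrix:
    """Region x sample normalized signal with the per-sample scale factors used."""

    values: pd.DataFrame                      # rows: region/gene ids, cols: samples
    scale_factors: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sample, factor in self.scale_factors.items():
            if factor <= 0:
                raise ValueError(f"scale factor for {sample} must be > 0")


class ZeroSpikeInError(ValueError):
    """A sample has no spike-in reads; normalization is undefined."""


def spikein_scale_factor(spikein_read_count: int,
                         reference_constant: float = DEFAULT_REFERENCE_CONSTANT) -> float:
    """reference_constant / spike-in count; the constant cancels between samples."""
    if spikein_read_count <= 0:
        raise ZeroSpikeInError("zero spike-in reads: cannot compute a scale factor")
    return reference_constant / spikein_read_count


def count_species(fragments: Sequence[FragmentRecord]) -> dict[str, int]:
    counts = {"target": 0, "spikein": 0}
    for fr in fragments:
        counts[fr.species] += 1
    return counts


def spikein_factors_from_fragments(
    fragments_by_sample: Mapping[str, Sequence[FragmentRecord]],
    reference_constant: float = DEFAULT_REFERENCE_CONSTANT,
) -> dict[str, float]:
    """Per-sample spike-in factors; errors name any sample lacking spike-in reads."""
    factors: dict[str, float] = {}
    for sample, frags in fragments_by_sample.items():
        n_spike = count_species(frags)["spikein"]
        if n_spike == 0:
            raise ZeroSpikeInError(f"sample {sample!r} has zero spike-in reads")
        factors[sample] = reference_constant / n_spike
    return factors


def promoter_signal_matrix(
    fragments_by_sample: Mapping[str, Sequence[FragmentRecord]],
    annotation: GenomeAnnotation,
    factors: Mapping[str, float],
    promoter_halfwidth: int = 2000,
) -> SignalMatrix:
    """Normalized promoter signal per gene and sample.

    Signal = (target-species fragments overlapping the promoter window)
    x sample factor; spike-in fragments never count as signal. A sample with
    no fragments yields a zero column with a logged warning.
    """
    missing = [s for s in fragments_by_sample if s not in factors]
    if missing:
        raise ValueError(f"scale factors missing for samples: {missing}")
    samples = list(fragments_by_sample)
    gene_ids = [g.gene_id for g in annotation.genes]
    values = pd.DataFrame(0.0, index=pd.Index(gene_ids, name="gene_id"), columns=samples)
    for sample in samples:
        frags = [fr for fr in fragments_by_sample[sample] if fr.species == "target"]
        if not frags:
            logger.warning("sample %s has no target fragments; zero signal column", sample)
            continue
        trees: dict[str, IntervalTree] = {}
        for i, fr in enumerate(frags):
            # unique payload: identical fragment intervals must count separately
            trees.setdefault(fr.chrom, IntervalTree()).addi(fr.start, fr.end, i)
        for g in annotation.genes:
            lo, hi = promoter_window(g.tss, promoter_halfwidth,
                                     annotation.chrom_sizes.get(g.chrom))
            tree = trees.get(g.chrom)
            if tree is not None and lo < hi:
                values.at[g.gene_id, sample] = len(tree.overlap(lo, hi)) * factors[sample]
    return SignalMatrix(values=values, scale_factors=dict(factors))
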