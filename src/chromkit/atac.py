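"""ATAC-seq fragment processing.

Transposase (Tn5) inserts as a homodimer and duplicates 9 bp of target
sequence, so insertion-site coordinates are corrected by +4 bp on the sense
strand and -5 bp on the antisense strand. Fragments are then segregated by
length into nucleosome-free (NFR), mono-, di- and tri-nucleosome classes, and
the NFR fraction is summarised as a coverage track over the central 80 bp of
each fragment, scaled to a fixed depth of 30 million nucleosome-free reads so
tracks are comparable across libraries.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .core import FragmentRecord

logger = logging.getLogger(__name__)

# Fragment-length classes (inclusive bounds). The sub-nucleosomal cutoff and
# the mono/di/tri bands follow the standard ATAC fragment-periodicity
# convention; lengths falling between bands are "other".
DEFAULT_CLASS_BOUNDS: dict[str, tuple[int, int]] = {
    "NFR": (1, 100),
    "mono": (180, 247),
    "di": (315, 473),
    "tri": (558, 615),
}


@dataclass
class AtacConfig:
    shift_plus: int = 4
    shift_minus: int = -5
    class_bounds: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_BOUNDS))
    center_width: int = 80
    scale_depth: float = 30_000_000.0
    reads_per_fragment: int = 2  # paired-end: one fragment = two reads

    def __post_init__(self) -> None:
        prev_hi = -1
        for name, (lo, hi) in self.class_bounds.items():
            if lo > hi:
                raise ValueError(f"class {name}: lower bound {lo} > upper bound {hi}")
            if lo <= prev_hi:
                raise ValueError("class bounds must be disjoint and increasing")
            prev_hi = hi


def tn5_shift(position: int, strand: str, cfg: AtacConfig | None = None) -> int:
    """Correct a single transposase cut site: +4 on '+', -5 on '-'."""
    cfg = cfg or AtacConfig()
    if strand == "+":
        return position + cfg.shift_plus
    if strand == "-":
        return position + cfg.shift_minus
    raise ValueError(f"strand must be '+' or '-', got {strand!r}")


def tn5_shift_fragment(fragment: FragmentRecord, cfg: AtacConfig | None = None
                       ) -> FragmentRecord | None:
    """Apply the Tn5 correction to both fragment ends.

    The 5' cut of the sense-strand read is the fragment start (+4) and the 5'
    cut of the antisense read is the fragment end (-5), so the fragment
    shrinks by 9 bp. Returns None (and counts a warning) if the shifted
    interval collapses.
    """
    cfg = cfg or AtacConfig()
    start = tn5_shift(fragment.start, "+", cfg)
    end = tn5_shift(fragment.end, "-", cfg)
    if start >= end:
        logger.warning("fragment [%d,%d) on %s collapsed by Tn5 shift; dropped",
                       fragment.start, fragment.end, fragment.chrom)
        return None
    return FragmentRecord(fragment.chrom, start, end,
                          sample_id=fragment.sample_id, species=fragment.species)


def shift_fragments(fragments: Iterable[FragmentRecord], cfg: AtacConfig | None = None
                    ) -> tuple[list[FragmentRecord], int]:
    """Shift a collection; returns (kept fragments, n_dropped)."""
    cfg = cfg or AtacConfig()
    kept: list[FragmentRecord] = []
    dropped = 0
    for fr in fragments:
        shifted = tn5_shift_fragment(fr, cfg)
        if shifted is None:
            dropped += 1
        else:
            kept.append(shifted)
    return kept, dropped


def classify_fragment(length: int, cfg: AtacConfig | None = None) -> str:
    """Assign a fragment length to NFR/mono/di/tri/other."""
    if length <= 0:
        raise ValueError(f"fragment length must be positive, got {length}")
    cfg = cfg or AtacConfig()
    for name, (lo, hi) in cfg.class_bounds.items():
        if lo <= length <= hi:
            return name
    return "other"


def classify_fragments(fragments: Sequence[FragmentRecord], cfg: AtacConfig | None = None
                       ) -> dict[str, list[FragmentRecord]]:
    """Partition fragments by nucleosome class; classes always sum to input."""
    cfg = cfg or AtacConfig()
    out: dict[str, list[FragmentRecord]] = {name: [] for name in cfg.class_bounds}
    out["other"] = []
    for fr in fragments:
        out[classify_fragment(fr.length, cfg)].append(fr)
    return out


class EmptyTrackError(ValueError):
    """Raised when no nucleosome-free fragments are available for a track."""


def nfr_track(fragments: Sequence[FragmentRecord], cfg: AtacConfig | None = None
              ) -> list[tuple[str, int, int, float]]:
    """Coverage of the central `center_width` bp of each NFR fragment.

    Values are scaled by scale_depth / (reads_per_fragment * n_NFR), so the
    track integral is center_width * scale_depth / reads_per_fragment
    regardless of library size. Returned as sorted bedGraph intervals.
    """
    cfg = cfg or AtacConfig()
    nfr = [fr for fr in fragments if classify_fragment(fr.length, cfg) == "NFR"]
    if not nfr:
        raise EmptyTrackError("no nucleosome-free fragments; cannot generate track")
    half = cfg.center_width // 2
    # breakpoint sweep per chromosome
    deltas: dict[str, dict[int, int]] = {}
    for fr in nfr:
        mid = (fr.start + fr.end) // 2
        lo, hi = mid - half, mid + (cfg.center_width - half)
        d = deltas.setdefault(fr.chrom, {})
        d[lo] = d.get(lo, 0) + 1
        d[hi] = d.get(hi, 0) - 1
    scale = cfg.scale_depth / (cfg.reads_per_fragment * len(nfr))
    track: list[tuple[str, int, int, float]] = []
    for chrom in sorted(deltas):
        depth = 0
        points = sorted(deltas[chrom].items())
        for (pos, delta), (nxt, _) in zip(points, points[1:] + [(None, 0)]):
            depth += delta
            if nxt is None:
                break
            if depth > 0 and nxt > pos:
                track.append((chrom, pos, nxt, depth * scale))
    return track


def track_integral(track: Iterable[tuple[str, int, int, float]]) -> float:
    return float(sum((end - start) * value for _, start, end, value in track))
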