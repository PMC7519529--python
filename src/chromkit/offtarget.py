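"""WGS-based CRISPR editing screen.

Given whole-genome alignments of edited clones and unedited controls, the
screen (i) enumerates candidate nuclease target sites: every 20-mer within a
configurable Hamming distance (default <= 4 substitutions) of the guide and
followed by a PAM (default NGG); (ii) calls small indels from CIGAR I/D
pileups at >= 5x coverage and >= 5% allele fraction and partitions them into
on-target / candidate off-target / artifact classes by cross-sample
validation against controls and predicted sites; (iii) detects long
deletions as runs (> 50 bp) of positions whose depth is improbably low
(mean Poisson lower-tail p < 1e-4) under a control-calibrated null; and
(iv) finds insertions as pairs of bidirectional soft-clip breakpoint
clusters (clip overhang > 10 bp) within a 5-bp window, absent from controls.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import AlignmentRecord

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

# IUPAC -> matching base set (used for PAM patterns)
_IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"), "B": frozenset("CGT"), "D": frozenset("AGT"),
    "H": frozenset("ACT"), "V": frozenset("ACG"), "N": frozenset("ACGT"),
}


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GuideSpec:
    protospacer: str
    pam: str = "NGG"
    max_mismatches: int = 4

    def __post_init__(self) -> None:
        if len(self.protospacer) != 20 or set(self.protospacer) - set("ACGT"):
            raise ValueError("protospacer must be a 20-nt A/C/G/T sequence")
        if set(self.pam) - set(_IUPAC):
            raise ValueError(f"PAM {self.pam!r} contains non-IUPAC symbols")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")


@dataclass
class ScreenConfig:
    """Thresholds of the screen; defaults reproduce the standard protocol."""

    min_coverage: int = 5          # indel pileup depth
    min_fraction: float = 0.05     # indel allele fraction
    max_mismatches: int = 4        # protospacer Hamming distance
    min_region: int = 50           # deletion run length (strictly greater)
    p_threshold: float = 1e-4      # deletion per-region mean p
    min_overhang: int = 10         # soft-clip overhang (strictly greater)
    pair_window: int = 5           # breakpoint pairing / cross-filter window
    site_proximity: int = 50       # indel-to-predicted-site distance
    null_window: int = 1000        # control window for the Poisson depth null


@dataclass(frozen=True)
class IndelCall:
    chrom: str
    pos: int
    ref_len: int
    alt_len: int
    coverage: int
    alt_fraction: float
    sample_id: str

    @property
    def key(self) -> tuple[str, int, int, int]:
        """Identity for cross-sample comparison."""
        return (self.chrom, self.pos, self.ref_len, self.alt_len)


@dataclass(frozen=True)
class BreakpointCluster:
    chrom: str
    position: int
    direction: str  # 'right_clip' or 'left_clip'
    support: int
    samples: frozenset[str]


# ---------------------------------------------------------------- site prediction


def _scan_forward(seq_codes: np.ndarray, guide_codes: np.ndarray,
                  pam_sets: list[frozenset[str]], seq: str,
                  max_mismatches: int) -> list[tuple[int, int]]:
    """(start, n_mismatches) of protospacer windows followed by a PAM.

    Vectorized: mismatch counts accumulated over the 20 guide offsets;
    ambiguous reference bases (code < 0) count as mismatches.
    """
    L = len(seq)
    glen = guide_codes.size
    plen = len(pam_sets)
    n_windows = L - glen - plen + 1
    if n_windows <= 0:
        return []
    mism = np.zeros(n_windows, dtype=np.int16)
    for offset in range(glen):
        codes = seq_codes[offset:offset + n_windows]
        mism += (codes != guide_codes[offset]) | (codes < 0)
    pam_ok = np.ones(n_windows, dtype=bool)
    for offset, allowed in enumerate(pam_sets):
        col = np.frombuffer(seq[glen + offset:glen + offset + n_windows].encode(), dtype=np.uint8)
        mask = np.zeros(256, dtype=bool)
        for b in allowed:
            mask[ord(b)] = True
        pam_ok &= mask[col]
    hits = np.nonzero((mism <= max_mismatches) & pam_ok)[0]
    return [(int(i), int(mism[i])) for i in hits]


_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    codes = np.full(arr.size, -1, dtype=np.int8)
    for base, code in _BASE_CODE.items():
        codes[arr == ord(base)] = code
    return codes


def predict_offtarget_sites(
    reference: Mapping[str, str],
    guide: GuideSpec,
) -> pd.DataFrame:
    """Exhaustive both-strand scan for protospacer+PAM matches.

    Returns a sorted table (chrom, start, strand, n_mismatches) where start
    is the forward-strand coordinate of the protospacer 20-mer's leftmost
    base. On '-' strand sites the PAM lies immediately 5' of `start` in
    forward coordinates.
    """
    if not reference:
        raise ValueError("reference must contain at least one sequence")
    glen = len(guide.protospacer)
    plen = len(guide.pam)
    guide_codes = np.array([_BASE_CODE[b] for b in guide.protospacer], dtype=np.int8)
    pam_sets = [_IUPAC[b] for b in guide.pam]
    rows = []
    for chrom in sorted(reference):
        seq = reference[chrom].upper()
        codes = _encode(seq)
        for start, mm in _scan_forward(codes, guide_codes, pam_sets, seq, guide.max_mismatches):
            rows.append((chrom, start, "+", mm))
        rc = _revcomp(seq)
        rc_codes = _encode(rc)
        L = len(seq)
        for start_rc, mm in _scan_forward(rc_codes, guide_codes, pam_sets, rc, guide.max_mismatches):
            # map the protospacer 20-mer back to forward coordinates
            rows.append((chrom, L - start_rc - glen, "-", mm))
    df = pd.DataFrame(rows, columns=["chrom", "start", "strand", "n_mismatches"])
    return df.sort_values(["chrom", "start", "strand"]).reset_index(drop=True)


# ---------------------------------------------------------------- coverage & indels


def compute_coverage(alignments: Sequence[AlignmentRecord],
                     chrom_sizes: Mapping[str, int]) -> dict[str, np.ndarray]:
    """Per-base aligned (M) depth via breakpoint accumulation."""
    cov = {chrom: np.zeros(size + 1, dtype=np.int32) for chrom, size in chrom_sizes.items()}
    for a in alignments:
        arr = cov.get(a.chrom)
        if arr is None:
            continue
        ref = a.pos
        for op, n in a.cigar:
            if op == "M":
                arr[ref] += 1
                arr[min(ref + n, arr.size - 1)] -= 1
                ref += n
            elif op == "D":
                ref += n
    return {chrom: np.cumsum(arr[:-1]).astype(np.int32) for chrom, arr in cov.items()}


def call_small_indels(
    alignments: Sequence[AlignmentRecord],
    chrom_sizes: Mapping[str, int],
    min_coverage: int = 5,
    min_fraction: float = 0.05,
    sample_id: str = "",
) -> list[IndelCall]:
    """Pileup of CIGAR I/D events filtered by depth and allele fraction.

    Identical indels share a (chrom, pos, ref_len, alt_len) key across
    samples. pos is the first deleted base for deletions and the reference
    base immediately after the insertion point for insertions.
    """
    support: dict[tuple[str, int, int, int], int] = {}
    for a in alignments:
        ref = a.pos
        for op, n in a.cigar:
            if op == "M":
                ref += n
            elif op == "D":
                key = (a.chrom, ref, n, 0)
                support[key] = support.get(key, 0) + 1
                ref += n
            elif op == "I":
                key = (a.chrom, ref, 0, n)
                support[key] = support.get(key, 0) + 1
    coverage = compute_coverage(alignments, chrom_sizes)
    calls: list[IndelCall] = []
    for (chrom, pos, ref_len, alt_len), n_alt in sorted(support.items()):
        depth_arr = coverage.get(chrom)
        if depth_arr is None or pos >= depth_arr.size:
            continue
        # depth at the flanking aligned base (deleted bases carry no M depth)
        depth = int(depth_arr[max(0, pos - 1)]) if ref_len else int(depth_arr[pos])
        depth = max(depth, n_alt)
        frac = n_alt / depth if depth else 0.0
        if depth >= min_coverage and frac >= min_fraction:
            calls.append(IndelCall(chrom, pos, ref_len, alt_len, depth, frac,
                                   sample_id or (alignments[0].sample_id if alignments else "")))
    return calls


def cross_sample_validate(
    calls_by_sample: Mapping[str, Sequence[IndelCall]],
    edited_samples: Sequence[str],
    control_samples: Sequence[str],
    predicted_sites: pd.DataFrame,
    on_target: tuple[str, int, int] | None = None,
    proximity: int = 50,
) -> dict[str, list[IndelCall]]:
    """Partition indel calls into on_target / candidate_offtarget / artifact / review.

    Calls present in any control are artifacts. Edited-only calls near the
    on-target locus are on_target; near a predicted site, candidate
    off-targets; anything else is kept in 'review' (flagged, never silently
    dropped). If on_target is None it is taken from the 0-mismatch predicted
    site(s).
    """
    if set(edited_samples) & set(control_samples):
        raise ValueError("edited and control sample groups must be disjoint")
    if not control_samples:
        raise ValueError("cross-sample validation requires >= 1 control sample")
    control_keys = {c.key for s in control_samples for c in calls_by_sample.get(s, [])}
    if on_target is None:
        exact = predicted_sites[predicted_sites["n_mismatches"] == 0]
        on_sites = [(r.chrom, int(r.start), int(r.start) + 23) for r in exact.itertuples()]
    else:
        on_sites = [on_target]
    site_pos = {
        chrom: grp["start"].to_numpy()
        for chrom, grp in predicted_sites.groupby("chrom")
    }
    out: dict[str, list[IndelCall]] = {
        "on_target": [], "candidate_offtarget": [], "artifact": [], "review": []}
    for sample in edited_samples:
        for call in calls_by_sample.get(sample, []):
            if call.key in control_keys:
                out["artifact"].append(call)
                continue
            if any(call.chrom == c and s - proximity <= call.pos <= e + proximity
                   for c, s, e in on_sites):
                out["on_target"].append(call)
                continue
            starts = site_pos.get(call.chrom)
            if starts is not None and np.any(
                    (call.pos >= starts - proximity) & (call.pos <= starts + 20 + proximity)):
                out["candidate_offtarget"].append(call)
            else:
                out["review"].append(call)
    return out


# ---------------------------------------------------------------- long deletions


def _tile_medians(depth: np.ndarray, window: int) -> np.ndarray:
    """Median depth of the non-overlapping `window`-bp tile containing each base."""
    n = depth.size
    out = np.empty(n, dtype=float)
    for start in range(0, n, window):
        out[start:start + window] = np.median(depth[start:start + window])
    return out


def deletion_scan(
    coverage_by_sample: Mapping[str, Mapping[str, np.ndarray]],
    edited_samples: Sequence[str],
    control_samples: Sequence[str],
    min_region: int = 50,
    p_threshold: float = 1e-4,
    null_window: int = 1000,
) -> pd.DataFrame:
    """Low-coverage regions in edited samples under a control-calibrated null.

    Per position, p = Poisson(lambda) lower tail of the edited depth, where
    lambda is the control median depth in the surrounding `null_window` tile.
    Maximal runs of positions with p <= p_threshold longer than `min_region`
    (strict) are reported, minus regions equally low in any control.
    """
    if not control_samples:
        raise ValueError("deletion scan requires >= 1 control sample")
    rows = []
    for edited in edited_samples:
        for chrom, depth in coverage_by_sample[edited].items():
            lam = np.zeros(depth.size, dtype=float)
            for control in control_samples:
                lam += _tile_medians(np.asarray(coverage_by_sample[control][chrom], dtype=float),
                                     null_window)
            lam /= len(control_samples)
            if np.all(lam <= 0):
                raise ValueError(f"control coverage on {chrom} is zero; cannot calibrate null")
            p = stats.poisson.cdf(np.asarray(depth, dtype=float), np.maximum(lam, 1e-9))
            low = p <= p_threshold
            for start, end in _runs(low):
                if end - start <= min_region:
                    continue
                mean_p = float(np.mean(p[start:end]))
                if mean_p >= p_threshold:
                    continue
                if _low_in_control(coverage_by_sample, control_samples, chrom,
                                   start, end, lam, p_threshold):
                    continue
                rows.append((edited, chrom, int(start), int(end), end - start, mean_p))
    return pd.DataFrame(rows, columns=["sample", "chrom", "start", "end", "length", "mean_p"])


def _low_in_control(coverage_by_sample, control_samples, chrom, start, end, lam,
                    p_threshold) -> bool:
    for control in control_samples:
        depth = np.asarray(coverage_by_sample[control][chrom][start:end], dtype=float)
        p = stats.poisson.cdf(depth, np.maximum(lam[start:end], 1e-9))
        if float(np.mean(p)) < p_threshold:
            return True
    return False


def _runs(mask: np.ndarray):
    """(start, end) of maximal True runs."""
    padded = np.concatenate(([False], mask, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.nonzero(diff == 1)[0]
    ends = np.nonzero(diff == -1)[0]
    return zip(starts, ends)


# ---------------------------------------------------------------- insertions


def softclip_breakpoints(alignments: Sequence[AlignmentRecord],
                         min_overhang: int = 10) -> list[tuple[str, int, str]]:
    """(chrom, position, direction) for clips with overhang strictly > min_overhang.

    A trailing clip yields a right_clip breakpoint at the reference end of
    the aligned block; a leading clip yields a left_clip at the alignment
    start.
    """
    points = []
    for a in alignments:
        first_op, first_len = a.cigar[0]
        last_op, last_len = a.cigar[-1]
        if first_op == "S" and first_len > min_overhang:
            points.append((a.chrom, a.pos, "left_clip"))
        if last_op == "S" and last_len > min_overhang and len(a.cigar) > 1:
            points.append((a.chrom, a.reference_end, "right_clip"))
    return points


def cluster_breakpoints(points: Sequence[tuple[str, int, str]], sample_id: str = ""
                        ) -> list[BreakpointCluster]:
    """Group breakpoints sharing an exact (chrom, position, direction)."""
    counts: dict[tuple[str, int, str], int] = {}
    for key in points:
        counts[key] = counts.get(key, 0) + 1
    return [BreakpointCluster(chrom, pos, direction, support, frozenset([sample_id]))
            for (chrom, pos, direction), support in sorted(counts.items())]


def insertion_breakpoints(
    alignments_by_sample: Mapping[str, Sequence[AlignmentRecord]],
    edited_samples: Sequence[str],
    control_samples: Sequence[str],
    min_overhang: int = 10,
    pair_window: int = 5,
) -> pd.DataFrame:
    """Insertion sites: paired bidirectional breakpoint clusters in edited samples.

    Clusters matching a control cluster of the same direction within
    pair_window are removed as non-specific; a site is emitted where a
    right_clip and a left_clip cluster lie within pair_window of each other.
    """
    control_points: dict[str, list[tuple[int, int]]] = {}  # chrom -> (pos, dir_idx)
    for sample in control_samples:
        for chrom, pos, direction in softclip_breakpoints(
                alignments_by_sample.get(sample, []), min_overhang):
            control_points.setdefault(chrom, []).append((pos, 0 if direction == "right_clip" else 1))
    rows = []
    for sample in edited_samples:
        clusters = cluster_breakpoints(
            softclip_breakpoints(alignments_by_sample.get(sample, []), min_overhang),
            sample_id=sample)
        kept: list[BreakpointCluster] = []
        for cl in clusters:
            dir_idx = 0 if cl.direction == "right_clip" else 1
            nearby_control = any(
                d == dir_idx and abs(pos - cl.position) <= pair_window
                for pos, d in control_points.get(cl.chrom, []))
            if not nearby_control:
                kept.append(cl)
        rights = [c for c in kept if c.direction == "right_clip"]
        lefts = [c for c in kept if c.direction == "left_clip"]
        for r in rights:
            for l in lefts:
                if l.chrom == r.chrom and abs(l.position - r.position) <= pair_window:
                    lo, hi = sorted((r.position, l.position))
                    rows.append((sample, r.chrom, lo, hi, r.support + l.support))
    return pd.DataFrame(rows, columns=["sample", "chrom", "left", "right", "support"]) \
        .drop_duplicates().reset_index(drop=True)


# ---------------------------------------------------------------- orchestration


@dataclass
class ScreenResult:
    predicted_sites: pd.DataFrame
    indel_partition: dict[str, list[IndelCall]]
    deletions: pd.DataFrame
    insertions: pd.DataFrame


def run_screen(
    reference: Mapping[str, str],
    alignments_by_sample: Mapping[str, Sequence[AlignmentRecord]],
    guide: GuideSpec,
    edited_samples: Sequence[str],
    control_samples: Sequence[str],
    config: ScreenConfig | None = None,
) -> ScreenResult:
    """Full screen: site prediction, indel validation, deletion and insertion scans."""
    cfg = config or ScreenConfig()
    chrom_sizes = {chrom: len(seq) for chrom, seq in reference.items()}
    guide = GuideSpec(guide.protospacer, guide.pam, cfg.max_mismatches)
    sites = predict_offtarget_sites(reference, guide)
    calls_by_sample = {
        sample: call_small_indels(aligns, chrom_sizes, cfg.min_coverage,
                                  cfg.min_fraction, sample_id=sample)
        for sample, aligns in alignments_by_sample.items()
    }
    partition = cross_sample_validate(calls_by_sample, edited_samples, control_samples,
                                      sites, proximity=cfg.site_proximity)
    coverage = {sample: compute_coverage(aligns, chrom_sizes)
                for sample, aligns in alignments_by_sample.items()}
    deletions = deletion_scan(coverage, edited_samples, control_samples,
                              cfg.min_region, cfg.p_threshold, cfg.null_window)
    insertions = insertion_breakpoints(alignments_by_sample, edited_samples,
                                       control_samples, cfg.min_overhang, cfg.pair_window)
    return ScreenResult(sites, partition, deletions, insertions)
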