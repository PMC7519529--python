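"""Synthetic data generators with known ground truth.

Every downstream stage of the toolkit is exercised against data produced
here: replicate peak sets with a controlled reproducible fraction,
negative-binomial count matrices with planted fold changes, ATAC
fragment-length mixtures, spike-in read proportions, and edited-genome
alignments carrying small indels, long deletions, and soft-clip-producing
insertions. Generators are byte-reproducible under a fixed seed.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .atac import DEFAULT_CLASS_BOUNDS
from .core import AlignmentRecord, FragmentRecord, Gene, GenomeAnnotation, Peak

# Layout constants: each gene occupies a 6 kb slot (2 kb body centred in it)
# so that +/-2 kb promoter windows of neighbouring genes never overlap.
GENE_SLOT = 6000
GENE_LENGTH = 2000
SPIKEIN_CHROM = "dm_chr1"
SPIKEIN_CHROM_LENGTH = 200_000


class ConfigurationError(ValueError):
    """A simulation configuration violates a stated constraint."""


@dataclass(frozen=True)
class PlantedEdit:
    """A genome edit planted in the edited sample's alignments.

    kind: 'small_indel' (CIGAR I/D at allele_fraction of overlapping reads),
    'long_deletion' (coverage removed over the span), or 'insertion'
    (paired bidirectional soft-clip breakpoints at `position`).
    indel_kind selects I vs D for small indels.
    """

    kind: str
    chrom: str
    position: int
    length: int
    allele_fraction: float = 1.0
    indel_kind: str = "deletion"

    def __post_init__(self) -> None:
        if self.kind not in ("small_indel", "long_deletion", "insertion"):
            raise ConfigurationError(f"unknown edit kind {self.kind!r}")
        if self.indel_kind not in ("deletion", "insertion"):
            raise ConfigurationError(f"indel_kind must be deletion/insertion, got {self.indel_kind!r}")
        if not 0.0 < self.allele_fraction <= 1.0:
            raise ConfigurationError("allele_fraction must be in (0, 1]")
        if self.length <= 0 or self.position < 0:
            raise ConfigurationError("edit position/length out of range")


@dataclass
class SimulationConfig:
    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 500_000
    n_genes: int = 100
    n_samples_per_group: int = 3
    de_fraction: float = 0.10
    planted_log2fc: float = 2.0
    nb_dispersion: float = 0.05
    fragment_class_mix: tuple[float, float, float, float] = (0.45, 0.35, 0.12, 0.05)
    spikein_fraction: float = 0.05
    planted_edits: tuple[PlantedEdit, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        for name, value in (("de_fraction", self.de_fraction),
                            ("spikein_fraction", self.spikein_fraction)):
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0,1], got {value}")
        if any(p < 0 for p in self.fragment_class_mix) or sum(self.fragment_class_mix) > 1 + 1e-12:
            raise ConfigurationError("fragment_class_mix entries must be >=0 and sum to <= 1")
        if self.nb_dispersion < 0:
            raise ConfigurationError("nb_dispersion must be >= 0")


# ---------------------------------------------------------------- genome


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    return bytes(alphabet[rng.integers(0, 4, size=length)]).decode()


def make_genome(config: SimulationConfig, with_sequence: bool = True
                ) -> tuple[GenomeAnnotation, dict[str, str]]:
    """Random genome: uniform A/C/G/T sequence plus non-overlapping genes.

    Genes are laid out on a 6 kb grid so promoters never collide; strands are
    random. Raises ConfigurationError when the genes cannot fit. Pass
    with_sequence=False to skip sequence generation when only the annotation
    is needed (large count simulations).
    """
    capacity = config.n_chroms * (config.chrom_length // GENE_SLOT)
    if config.n_genes > capacity:
        raise ConfigurationError(
            f"capacity violation: n_genes*{GENE_SLOT} must be <= n_chroms*chrom_length "
            f"({config.n_genes} genes > {capacity} slots)")
    rng = np.random.default_rng(config.seed)
    chroms = [f"chrS{i + 1}" for i in range(config.n_chroms)]
    chrom_sizes = {c: config.chrom_length for c in chroms}
    sequences = {
        c: _random_sequence(rng, config.chrom_length) if with_sequence else ""
        for c in chroms
    }
    slots_per_chrom = config.chrom_length // GENE_SLOT
    genes: list[Gene] = []
    for i in range(config.n_genes):
        chrom = chroms[i // slots_per_chrom]
        slot = i % slots_per_chrom
        start = slot * GENE_SLOT + (GENE_SLOT - GENE_LENGTH) // 2
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(Gene(f"gene_{i + 1:04d}", chrom, start, start + GENE_LENGTH, strand))
    return GenomeAnnotation(chrom_sizes, genes), sequences


# ---------------------------------------------------------------- peak replicates


def simulate_peak_replicates(
    annotation: GenomeAnnotation,
    n_true: int = 100,
    reproducible_fraction: float = 0.6,
    q_strong: float = 0.05,
    q_weak: float = 0.5,
    seed: int = 0,
    peak_width: int = 400,
    n_noise: int | None = None,
) -> tuple[list[Peak], list[Peak], pd.DataFrame]:
    """Two replicate peak sets with a controlled reproducible fraction.

    A `reproducible_fraction` subset of true sites is called at q <= q_strong
    in replicate 1 and at q <= q_weak in replicate 2 (these should survive
    finalization); the remainder appear, stringently, in exactly one
    replicate. Noise sites called leniently in both replicates are added to
    exercise the rule's complement. The truth table records the expected
    merged interval of every survivor.
    """
    if not 0.0 <= reproducible_fraction <= 1.0:
        raise ConfigurationError("reproducible_fraction must lie in [0,1]")
    rng = np.random.default_rng(seed)
    if n_noise is None:
        n_noise = n_true // 5
    slot = peak_width + 1600  # spacing so distinct sites never merge
    total_slots = sum(size // slot for size in annotation.chrom_sizes.values())
    if n_true + n_noise > total_slots:
        raise ConfigurationError("too many peaks for the genome size")
    positions: list[tuple[str, int]] = []
    for chrom in sorted(annotation.chrom_sizes):
        for i in range(annotation.chrom_sizes[chrom] // slot):
            positions.append((chrom, i * slot + 100))
    chosen = rng.choice(len(positions), size=n_true + n_noise, replace=False)

    n_rep = int(round(n_true * reproducible_fraction))
    reproducible = np.zeros(n_true, dtype=bool)
    reproducible[rng.choice(n_true, size=n_rep, replace=False)] = True

    rep1: list[Peak] = []
    rep2: list[Peak] = []
    truth_rows = []
    for i in range(n_true):
        chrom, start = positions[chosen[i]]
        end = start + peak_width
        if reproducible[i]:
            q1 = float(rng.uniform(1e-6, q_strong))
            # partner call: sometimes stringent too, sometimes lenient-only
            q2 = float(rng.uniform(1e-6, q_strong)) if rng.random() < 0.5 \
                else float(rng.uniform(q_strong * 1.01, q_weak))
            jitter = int(rng.integers(-50, 51))
            s2, e2 = start + jitter, end + jitter
            rep1.append(Peak(chrom, start, end, q_value=q1, sample_id="rep1"))
            rep2.append(Peak(chrom, s2, e2, q_value=q2, sample_id="rep2"))
            # survivors are the stringent calls; a lenient-only partner
            # supports survival but contributes no interval of its own
            if q2 <= q_strong:
                truth_rows.append((chrom, min(start, s2), max(end, e2), True))
            else:
                truth_rows.append((chrom, start, end, True))
        else:
            q = float(rng.uniform(1e-6, q_strong))
            target = rep1 if i % 2 == 0 else rep2
            target.append(Peak(chrom, start, end, q_value=q,
                               sample_id="rep1" if i % 2 == 0 else "rep2"))
            truth_rows.append((chrom, start, end, False))
    for j in range(n_noise):
        chrom, start = positions[chosen[n_true + j]]
        end = start + peak_width
        for name, lst in (("rep1", rep1), ("rep2", rep2)):
            q = float(rng.uniform(q_strong * 1.01, q_weak))
            lst.append(Peak(chrom, start, end, q_value=q, sample_id=name))
    truth = pd.DataFrame(truth_rows, columns=["chrom", "start", "end", "reproducible"])
    return rep1, rep2, truth


# ---------------------------------------------------------------- counts


def simulate_counts(
    annotation: GenomeAnnotation,
    config: SimulationConfig,
    seed: int | None = None,
) -> tuple[pd.DataFrame, dict[str, str], pd.DataFrame]:
    """Negative-binomial count matrix with planted fold changes.

    Gene means are log-uniform on [20, 2000]; variance = mu + mu^2 * disp.
    A `de_fraction` subset is shifted by planted_log2fc in the KO group,
    half up and half down; per-sample library factors are drawn uniform
    [0.7, 1.3]. Returns (counts, sample->group map, truth table).
    """
    if config.n_samples_per_group < 2:
        raise ConfigurationError("need >= 2 samples per group")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    gene_ids = [g.gene_id for g in annotation.genes]
    n = len(gene_ids)
    mu = np.exp(rng.uniform(math.log(20.0), math.log(2000.0), size=n))

    n_de = int(round(config.de_fraction * n))
    de_idx = rng.choice(n, size=n_de, replace=False)
    direction = np.full(n, "ns", dtype=object)
    lfc = np.zeros(n)
    half = n_de // 2
    direction[de_idx[:half]] = "up"
    lfc[de_idx[:half]] = config.planted_log2fc
    direction[de_idx[half:]] = "down"
    lfc[de_idx[half:]] = -config.planted_log2fc

    samples = [f"WT_{i + 1}" for i in range(config.n_samples_per_group)] + \
              [f"KO_{i + 1}" for i in range(config.n_samples_per_group)]
    groups = {s: s.split("_")[0] for s in samples}
    lib = rng.uniform(0.7, 1.3, size=len(samples))

    counts = np.empty((n, len(samples)), dtype=np.int64)
    for j, sample in enumerate(samples):
        mean_j = mu * lib[j]
        if groups[sample] == "KO":
            mean_j = mean_j * np.exp2(lfc)
        if config.nb_dispersion < 1e-8:
            counts[:, j] = rng.poisson(mean_j)
        else:
            size = 1.0 / config.nb_dispersion
            p = size / (size + mean_j)
            counts[:, j] = rng.negative_binomial(size, p)
    counts_df = pd.DataFrame(counts, index=pd.Index(gene_ids, name="feature_id"),
                             columns=samples)
    truth = pd.DataFrame({
        "gene_id": gene_ids,
        "is_de": direction != "ns",
        "direction": direction,
        "true_log2fc": lfc,
        "base_mean": mu,
    })
    return counts_df, groups, truth


# ---------------------------------------------------------------- fragments

_OTHER_RANGE = (110, 170)  # lengths between NFR and mono bands


def simulate_fragments(
    annotation: GenomeAnnotation,
    config: SimulationConfig,
    n_fragments: int = 10_000,
    sample_id: str = "S1",
    seed: int | None = None,
) -> list[FragmentRecord]:
    """Fragment-length mixture over NFR/mono/di/tri/other classes.

    Lengths are drawn uniformly within each class's (disjoint) band; a
    binomial `spikein_fraction` of fragments is assigned to the spike-in
    species (distinct 'dm_' chromosome); positions are uniform.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    classes = list(DEFAULT_CLASS_BOUNDS) + ["other"]
    probs = list(config.fragment_class_mix) + [1.0 - sum(config.fragment_class_mix)]
    bands = {**DEFAULT_CLASS_BOUNDS, "other": _OTHER_RANGE}
    chroms = sorted(annotation.chrom_sizes)
    fragments: list[FragmentRecord] = []
    for _ in range(n_fragments):
        cls = classes[rng.choice(len(classes), p=probs)]
        lo, hi = bands[cls]
        length = int(rng.integers(lo, hi + 1))
        if rng.random() < config.spikein_fraction:
            chrom, size, species = SPIKEIN_CHROM, SPIKEIN_CHROM_LENGTH, "spikein"
        else:
            chrom = chroms[rng.integers(len(chroms))]
            size, species = annotation.chrom_sizes[chrom], "target"
        start = int(rng.integers(0, max(1, size - length)))
        fragments.append(FragmentRecord(chrom, start, start + length,
                                        sample_id=sample_id, species=species))
    return fragments


def simulate_promoter_fragments(
    annotation: GenomeAnnotation,
    groups: Mapping[str, str],
    boosted_genes: Sequence[str] = (),
    base_fragments_per_promoter: float = 30.0,
    boost_fold: float = 3.0,
    spikein_mean: float = 2000.0,
    fragment_length: int = 150,
    seed: int = 0,
) -> dict[str, list[FragmentRecord]]:
    """CUT&RUN-like promoter-concentrated fragments with planted group effects.

    Each sample has a random capture-efficiency factor applied to target and
    spike-in counts alike (spike-in normalization must cancel it). Genes in
    `boosted_genes` receive `boost_fold` more promoter fragments in KO
    samples. Promoter fragments are centred within +/-500 bp of the TSS.
    """
    rng = np.random.default_rng(seed)
    out: dict[str, list[FragmentRecord]] = {}
    for sample in groups:
        efficiency = float(rng.uniform(0.5, 1.5))
        frags: list[FragmentRecord] = []
        for g in annotation.genes:
            lam = base_fragments_per_promoter * efficiency
            if groups[sample] == "KO" and g.gene_id in boosted_genes:
                lam *= boost_fold
            for _ in range(rng.poisson(lam)):
                center = g.tss + int(rng.integers(-500, 501))
                start = max(0, center - fragment_length // 2)
                frags.append(FragmentRecord(g.chrom, start, start + fragment_length,
                                            sample_id=sample, species="target"))
        for _ in range(rng.poisson(spikein_mean * efficiency)):
            start = int(rng.integers(0, SPIKEIN_CHROM_LENGTH - fragment_length))
            frags.append(FragmentRecord(SPIKEIN_CHROM, start, start + fragment_length,
                                        sample_id=sample, species="spikein"))
        out[sample] = frags
    return out


# ---------------------------------------------------------------- WGS alignments


def simulate_wgs_alignments(
    chrom_sizes: Mapping[str, int],
    config: SimulationConfig,
    depth: int = 30,
    read_length: int = 100,
    edited_samples: Sequence[str] = ("KO",),
    control_samples: Sequence[str] = ("WT",),
    sequences: Mapping[str, str] | None = None,
    seed: int | None = None,
) -> tuple[dict[str, list[AlignmentRecord]], tuple[PlantedEdit, ...]]:
    """Uniform-coverage alignments with planted edits in the edited samples.

    Control samples are perfect-match tilings at the stated depth. In edited
    samples: small indels appear as CIGAR I/D in an allele_fraction of
    overlapping reads; long deletions remove all reads overlapping their
    span; insertions convert allele_fraction of breakpoint-crossing reads
    into soft-clipped records whose clip ends (right_clip) or starts
    (left_clip) at the insertion point.
    """
    for edit in config.planted_edits:
        size = chrom_sizes.get(edit.chrom)
        if size is None or edit.position + (edit.length if edit.kind == "long_deletion" else 0) > size \
                or edit.position >= size:
            raise ConfigurationError(
                f"edit at {edit.chrom}:{edit.position} (+{edit.length}) outside chromosome bounds")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    step = read_length / depth
    out: dict[str, list[AlignmentRecord]] = {}
    for sample in list(control_samples) + list(edited_samples):
        edited = sample in edited_samples
        records: list[AlignmentRecord] = []
        for chrom in sorted(chrom_sizes):
            size = chrom_sizes[chrom]
            n_reads = int((size - read_length) / step) + 1
            starts = (np.arange(n_reads) * step).astype(np.int64)
            for k, a in enumerate(starts):
                a = int(a)
                rec = _make_read(chrom, a, read_length, sample, f"{sample}_{chrom}_{k}",
                                 config.planted_edits if edited else (), rng, sequences)
                if rec is not None:
                    records.append(rec)
        out[sample] = records
    return out, tuple(config.planted_edits)


def _read_seq(sequences: Mapping[str, str] | None, chrom: str, start: int, length: int,
              rng: np.random.Generator) -> str:
    if sequences is not None and sequences.get(chrom):
        seq = sequences[chrom][start:start + length]
        if len(seq) >= length:
            return seq
    return _random_sequence(rng, length)


def _make_read(chrom: str, a: int, read_length: int, sample: str, read_id: str,
               edits: Sequence[PlantedEdit], rng: np.random.Generator,
               sequences: Mapping[str, str] | None) -> AlignmentRecord | None:
    span_end = a + read_length
    strand = "+" if rng.random() < 0.5 else "-"
    for edit in edits:
        if edit.chrom != chrom:
            continue
        if edit.kind == "long_deletion":
            if a < edit.position + edit.length and span_end > edit.position:
                return None  # coverage removed over the deleted span
        elif edit.kind == "insertion":
            if a < edit.position < span_end and rng.random() < edit.allele_fraction:
                x = edit.position - a  # left aligned part
                r = read_length - x    # right part
                if x >= r:  # aligned left of breakpoint, trailing clip
                    cigar = (("M", x), ("S", r))
                    pos = a
                else:       # aligned right of breakpoint, leading clip
                    cigar = (("S", x), ("M", r))
                    pos = edit.position
                seq = _read_seq(sequences, chrom, pos - (x if x < r else 0), read_length, rng)
                return AlignmentRecord(chrom, pos, cigar, strand=strand,
                                       sample_id=sample, read_id=read_id, seq=seq)
        elif edit.kind == "small_indel":
            x = edit.position - a
            if 1 <= x <= read_length - 1 and rng.random() < edit.allele_fraction:
                if edit.indel_kind == "deletion":
                    cigar = (("M", x), ("D", edit.length), ("M", read_length - x))
                else:
                    if x + edit.length > read_length - 1:
                        continue
                    cigar = (("M", x), ("I", edit.length), ("M", read_length - x - edit.length))
                seq = _read_seq(sequences, chrom, a, read_length, rng)
                return AlignmentRecord(chrom, a, cigar, strand=strand,
                                       sample_id=sample, read_id=read_id, seq=seq)
    seq = _read_seq(sequences, chrom, a, read_length, rng)
    return AlignmentRecord(chrom, a, (("M", read_length),), strand=strand,
                           sample_id=sample, read_id=read_id, seq=seq)


def plant_protospacer_sites(
    sequence: str,
    guide: str,
    n_sites: int,
    seed: int = 0,
    pam: str = "AGG",
    max_mismatches: int = 4,
) -> tuple[str, pd.DataFrame]:
    """Embed protospacer+PAM copies (0..max_mismatches substitutions) in a sequence.

    Sites alternate between strands and are spaced evenly; returns the edited
    sequence and a truth table (start, strand, n_mismatches) where start is
    the forward-strand coordinate of the protospacer 20-mer.
    """
    from .offtarget import _revcomp  # local import to avoid a cycle at module load

    rng = np.random.default_rng(seed)
    L = len(sequence)
    site_len = len(guide) + len(pam)
    spacing = L // (n_sites + 1)
    if spacing <= site_len + 10:
        raise ConfigurationError("sequence too short for requested number of sites")
    seq = list(sequence)
    rows = []
    bases = "ACGT"
    for i in range(n_sites):
        n_mm = i % (max_mismatches + 1)
        proto = list(guide)
        mm_pos = rng.choice(len(guide), size=n_mm, replace=False)
        for p in mm_pos:
            proto[p] = rng.choice([b for b in bases if b != proto[p]])
        strand = "+" if i % 2 == 0 else "-"
        insert_at = (i + 1) * spacing
        payload = "".join(proto) + pam
        if strand == "-":
            payload = _revcomp(payload)
            proto_start = insert_at + len(pam)
        else:
            proto_start = insert_at
        seq[insert_at:insert_at + site_len] = list(payload)
        rows.append((proto_start, strand, n_mm))
    truth = pd.DataFrame(rows, columns=["start", "strand", "n_mismatches"])
    return "".join(seq), truth
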