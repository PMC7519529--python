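"""Core domain types shared across the toolkit.

Coordinates are 0-based, half-open throughout the in-memory model; 1-based
formats (GTF, SAM) are converted at the I/O boundary.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable


@dataclass(frozen=True)
class Gene:
    """A strand-aware gene record anchoring TSS-based windows."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str  # '+' or '-'

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"gene {self.gene_id}: invalid interval [{self.start},{self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}")

    @property
    def tss(self) -> int:
        """Transcription start site: start for '+' genes, end-1 for '-' genes."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class GenomeAnnotation:
    """Chromosome sizes plus gene records."""

    chrom_sizes: dict[str, int]
    genes: list[Gene] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise ValueError(f"duplicate gene_id {g.gene_id}")
            seen.add(g.gene_id)
            size = self.chrom_sizes.get(g.chrom)
            if size is None:
                raise ValueError(f"gene {g.gene_id} on unknown chromosome {g.chrom}")
            if g.end > size:
                raise ValueError(f"gene {g.gene_id} extends past end of {g.chrom}")

    def genes_by_chrom(self) -> dict[str, list[Gene]]:
        out: dict[str, list[Gene]] = {}
        for g in self.genes:
            out.setdefault(g.chrom, []).append(g)
        return out


@dataclass(frozen=True)
class Peak:
    """Half-open genomic interval with score and significance."""

    chrom: str
    start: int
    end: int
    score: float = 0.0
    q_value: float = 1.0
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"peak [{self.start},{self.end}) on {self.chrom}: start must be < end")
        if not 0.0 <= self.q_value <= 1.0:
            raise ValueError(f"q_value {self.q_value} outside [0,1]")

    def overlaps(self, other: "Peak") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class FragmentRecord:
    """A sequenced paired-end fragment (ATAC or CUT&RUN)."""

    chrom: str
    start: int
    end: int
    sample_id: str = ""
    species: str = "target"  # 'target' or 'spikein'

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"fragment [{self.start},{self.end}): start must be < end")
        if self.species not in ("target", "spikein"):
            raise ValueError(f"species must be 'target' or 'spikein', got {self.species!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


# CIGAR operation codes used by the off-target screen.
CIGAR_OPS = frozenset("MIDS")


@dataclass(frozen=True)
class AlignmentRecord:
    """Minimal SAM-like alignment supporting indel, coverage and soft-clip analysis.

    `cigar` is a tuple of (op, length) with op in {M, I, D, S}; S only at the
    ends. `pos` is the 0-based leftmost *aligned* reference coordinate (soft
    clips consume no reference).
    """

    chrom: str
    pos: int
    cigar: tuple[tuple[str, int], ...]
    strand: str = "+"
    sample_id: str = ""
    mapq: int = 60
    read_id: str = ""
    seq: str = ""

    def __post_init__(self) -> None:
        ops = [op for op, _ in self.cigar]
        if not ops:
            raise ValueError("empty CIGAR")
        for i, op in enumerate(ops):
            if op not in CIGAR_OPS:
                raise ValueError(f"unsupported CIGAR op {op!r}")
            if op == "S" and i not in (0, len(ops) - 1):
                raise ValueError("S operations allowed only at CIGAR ends")

    @property
    def query_length(self) -> int:
        return sum(n for op, n in self.cigar if op in ("M", "I", "S"))

    @property
    def reference_length(self) -> int:
        return sum(n for op, n in self.cigar if op in ("M", "D"))

    @property
    def reference_end(self) -> int:
        """One past the last aligned reference base."""
        return self.pos + self.reference_length

    def cigar_string(self) -> str:
        return "".join(f"{n}{op}" for op, n in self.cigar)


def sort_peaks(peaks: Iterable[Peak]) -> list[Peak]:
    return sorted(peaks, key=lambda p: (p.chrom, p.start, p.end))
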