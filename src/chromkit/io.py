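"""Readers and writers for the plain-text genomic formats the toolkit consumes.

All in-memory coordinates are 0-based half-open. GTF is converted from its
native 1-based inclusive convention on read and back on write; SAM POS
likewise. Peaks travel as BED6 plus a q-value column, or as ENCODE narrowPeak
(whose 9th column stores -log10 q and is converted on read).
"""
from __future__ import annotations

import os
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import AlignmentRecord, FragmentRecord, Gene, GenomeAnnotation, Peak

# ---------------------------------------------------------------- FASTA


def write_fasta(sequences: Mapping[str, str], path: str | os.PathLike) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------- GTF


def write_gtf(annotation: GenomeAnnotation, path: str | os.PathLike) -> None:
    """Write gene features as 9-column GTF (1-based inclusive)."""
    with open(path, "w") as fh:
        for g in annotation.genes:
            attrs = f'gene_id "{g.gene_id}";'
            fh.write(
                f"{g.chrom}\tchromkit\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )


def read_gtf(path: str | os.PathLike, chrom_sizes: Mapping[str, int] | None = None) -> GenomeAnnotation:
    """Read gene features from GTF.

    If chrom_sizes is omitted, sizes are inferred as the maximum gene end per
    chromosome (sufficient for window clipping on fixtures).
    """
    genes: list[Gene] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9 or fields[2] != "gene":
                continue
            chrom, _, _, start1, end1, _, strand, _, attrs = fields[:9]
            gene_id = ""
            for item in attrs.split(";"):
                item = item.strip()
                if item.startswith("gene_id"):
                    gene_id = item.split(None, 1)[1].strip('"')
                    break
            if not gene_id:
                raise ValueError(f"GTF record without gene_id: {line.rstrip()}")
            genes.append(Gene(gene_id, chrom, int(start1) - 1, int(end1), strand))
    if chrom_sizes is None:
        chrom_sizes = {}
        for g in genes:
            chrom_sizes[g.chrom] = max(chrom_sizes.get(g.chrom, 0), g.end)  # type: ignore[index]
    return GenomeAnnotation(dict(chrom_sizes), genes)


def write_chrom_sizes(chrom_sizes: Mapping[str, int], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for chrom, size in chrom_sizes.items():
            fh.write(f"{chrom}\t{size}\n")


def read_chrom_sizes(path: str | os.PathLike) -> dict[str, int]:
    out: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if line.strip():
                chrom, size = line.split()[:2]
                out[chrom] = int(size)
    return out


# ---------------------------------------------------------------- peaks (BED6+q / narrowPeak)


def write_peaks_bed(peaks: Sequence[Peak], path: str | os.PathLike) -> None:
    """BED6 plus a 7th q-value column."""
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            name = p.sample_id or f"peak_{i}"
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{name}\t{p.score:g}\t.\t{p.q_value:g}\n")


def read_peaks_bed(path: str | os.PathLike, sample_id: str = "") -> list[Peak]:
    peaks: list[Peak] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            q = float(f[6]) if len(f) > 6 else 1.0
            score = float(f[4]) if len(f) > 4 and f[4] != "." else 0.0
            peaks.append(Peak(f[0], int(f[1]), int(f[2]), score=score, q_value=q,
                              sample_id=sample_id or (f[3] if len(f) > 3 else "")))
    return peaks


def read_narrowpeak(path: str | os.PathLike, sample_id: str = "") -> list[Peak]:
    """ENCODE narrowPeak; column 9 holds -log10(q) and is converted to q."""
    peaks: list[Peak] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            neglog_q = float(f[8])
            q = 1.0 if neglog_q < 0 else min(1.0, 10.0 ** (-neglog_q))
            peaks.append(Peak(f[0], int(f[1]), int(f[2]), score=float(f[4]),
                              q_value=q, sample_id=sample_id or f[3]))
    return peaks


# ---------------------------------------------------------------- BEDPE fragments

_MATE_LEN = 50


def write_fragments_bedpe(fragments: Sequence[FragmentRecord], path: str | os.PathLike) -> None:
    """Fragments as BEDPE: mates are the first/last min(50, len) bases."""
    with open(path, "w") as fh:
        for i, fr in enumerate(fragments):
            m = min(_MATE_LEN, fr.length)
            name = f"{fr.sample_id or 'frag'}:{fr.species}:{i}"
            fh.write(
                f"{fr.chrom}\t{fr.start}\t{fr.start + m}\t"
                f"{fr.chrom}\t{fr.end - m}\t{fr.end}\t{name}\t.\t+\t-\n"
            )


def read_fragments_bedpe(path: str | os.PathLike, sample_id: str = "") -> list[FragmentRecord]:
    frags: list[FragmentRecord] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            name = f[6] if len(f) > 6 else ""
            parts = name.split(":")
            species = parts[1] if len(parts) > 2 and parts[1] in ("target", "spikein") else "target"
            sample = sample_id or (parts[0] if parts else "")
            frags.append(FragmentRecord(f[0], int(f[1]), int(f[5]), sample_id=sample, species=species))
    return frags


# ---------------------------------------------------------------- SAM


def write_sam(alignments: Sequence[AlignmentRecord], chrom_sizes: Mapping[str, int],
              path: str | os.PathLike) -> None:
    """Minimal-header text SAM. Unstranded fields beyond the screen's needs are defaulted."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        for chrom, size in chrom_sizes.items():
            fh.write(f"@SQ\tSN:{chrom}\tLN:{size}\n")
        for i, a in enumerate(sorted(alignments, key=lambda r: (r.chrom, r.pos))):
            flag = 16 if a.strand == "-" else 0
            qname = a.read_id or f"{a.sample_id or 'read'}_{i}"
            seq = a.seq or "A" * a.query_length
            fh.write(
                f"{qname}\t{flag}\t{a.chrom}\t{a.pos + 1}\t{a.mapq}\t{a.cigar_string()}\t"
                f"*\t0\t0\t{seq}\t*\n"
            )


_OP_CODE_TO_CHAR = {0: "M", 1: "I", 2: "D", 4: "S"}


def read_sam(path: str | os.PathLike, sample_id: str = "") -> list[AlignmentRecord]:
    """Parse a text SAM via pysam into AlignmentRecords (M/I/D/S ops only)."""
    records: list[AlignmentRecord] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for read in sam.fetch(until_eof=True):
            if read.is_unmapped or read.cigartuples is None:
                continue
            cigar = []
            for code, length in read.cigartuples:
                char = _OP_CODE_TO_CHAR.get(code)
                if char is None:
                    raise ValueError(f"unsupported CIGAR op code {code} in {read.query_name}")
                cigar.append((char, length))
            records.append(AlignmentRecord(
                chrom=read.reference_name,
                pos=read.reference_start,
                cigar=tuple(cigar),
                strand="-" if read.is_reverse else "+",
                sample_id=sample_id,
                mapq=read.mapping_quality,
                read_id=read.query_name,
                seq=read.query_sequence or "",
            ))
    return records


# ---------------------------------------------------------------- matrices / tracks


def write_counts_tsv(counts: pd.DataFrame, path: str | os.PathLike) -> None:
    counts.to_csv(path, sep="\t", index_label="feature_id")


def read_counts_tsv(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_sample_sheet(groups: Mapping[str, str], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tgroup\n")
        for sample, group in groups.items():
            fh.write(f"{sample}\t{group}\n")


def read_sample_sheet(path: str | os.PathLike) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["sample_id"].astype(str), df["group"].astype(str)))


def write_bedgraph(intervals: Iterable[tuple[str, int, int, float]], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, value in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{value:g}\n")


def read_bedgraph(path: str | os.PathLike) -> list[tuple[str, int, int, float]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, start, end, value = line.split()[:4]
            out.append((chrom, int(start), int(end), float(value)))
    return out
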