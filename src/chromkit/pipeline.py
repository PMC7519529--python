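"""End-to-end orchestration: peaks -> gene assignment -> differential -> enrichment.

A single config drives the integration run; every threshold used is recorded
in a machine-readable manifest so each reported number is reproducible from
the manifest alone. Reports are written deterministically (no timestamps):
identical inputs give byte-identical outputs.
"""
from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .differential import run_differential
from .enrichment import hypergeom_overlap, overlap_report_table
from .intervals import AssignmentConfig, assign_bound_genes, finalize_reproducible_peaks
from .io import (read_counts_tsv, read_gtf, read_peaks_bed, read_sample_sheet,
                 write_peaks_bed)

logger = logging.getLogger(__name__)


class PipelineInputError(ValueError):
    """An input path is missing or does not parse; message names the input."""


class PipelineStageError(RuntimeError):
    """A stage failed; message names the stage."""


@dataclass
class PipelineConfig:
    output_dir: str = "chromkit_out"
    annotation: str = ""               # GTF path
    peak_replicates: list[str] = field(default_factory=list)  # BED6+q per replicate
    counts: str = ""                   # features x samples TSV
    sample_sheet: str = ""             # sample_id/group TSV
    q_strong: float = 0.05
    q_weak: float = 0.5
    promoter_halfwidth: int = 2000
    distal_min: int = 2000
    distal_max: int = 50000
    fdr_max: float = 0.05
    min_fold: float = 2.0
    reference_group: str = "WT"
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise PipelineInputError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def _require(path: str, name: str) -> str:
    if not path:
        raise PipelineInputError(f"missing required input: {name}")
    if not Path(path).exists():
        raise PipelineInputError(f"input {name} not found: {path}")
    return path


def run_integration(config: PipelineConfig) -> dict[str, Any]:
    """finalize -> assign_bound_genes -> differential -> threshold calls -> overlap.

    Returns a bundle of in-memory results and writes TSV reports plus a
    manifest to config.output_dir. Any stage failure raises
    PipelineStageError naming the stage.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    _require(config.annotation, "annotation")
    for p in config.peak_replicates:
        _require(p, "peak_replicates")
    _require(config.counts, "counts")
    _require(config.sample_sheet, "sample_sheet")
    if len(config.peak_replicates) < 2:
        raise PipelineInputError("peak_replicates: need >= 2 replicate peak files")

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    try:
        annotation = read_gtf(config.annotation)
        replicate_calls = [read_peaks_bed(p, sample_id=f"rep{i + 1}")
                           for i, p in enumerate(config.peak_replicates)]
        counts = read_counts_tsv(config.counts)
        groups = read_sample_sheet(config.sample_sheet)
    except PipelineInputError:
        raise
    except Exception as exc:  # noqa: BLE001 - reported as a named input failure
        raise PipelineInputError(f"failed to parse inputs: {exc}") from exc

    stage = "finalize_reproducible_peaks"
    try:
        final_peaks = finalize_reproducible_peaks(
            replicate_calls, q_strong=config.q_strong, q_weak=config.q_weak)
        write_peaks_bed(final_peaks, outdir / "final_peaks.bed")

        stage = "assign_bound_genes"
        cfg = AssignmentConfig(promoter_halfwidth=config.promoter_halfwidth,
                               distal_min=config.distal_min, distal_max=config.distal_max)
        bound = assign_bound_genes(final_peaks, annotation, cfg)
        (outdir / "bound_genes.txt").write_text("\n".join(sorted(bound)) + "\n")

        stage = "differential"
        results = run_differential(counts, groups, reference_group=config.reference_group,
                                   fdr_max=config.fdr_max, min_fold=config.min_fold)
        results.to_csv(outdir / "differential.tsv", sep="\t", index=False)
        up = set(results.loc[results["call"] == "up", "feature_id"])
        down = set(results.loc[results["call"] == "down", "feature_id"])
        (outdir / "genes_up.txt").write_text("\n".join(sorted(up)) + "\n")
        (outdir / "genes_down.txt").write_text("\n".join(sorted(down)) + "\n")

        stage = "hypergeom_overlap"
        universe = set(counts.index.astype(str))
        bound_in_universe = bound & universe
        reports = [
            hypergeom_overlap(universe, bound_in_universe, down, label="down_vs_bound"),
            hypergeom_overlap(universe, bound_in_universe, up, label="up_vs_bound"),
            hypergeom_overlap(universe, bound_in_universe, up | down, label="all_de_vs_bound"),
        ]
        table = overlap_report_table(reports)
        table.to_csv(outdir / "overlap_report.tsv", sep="\t", index=False)
    except Exception as exc:
        raise PipelineStageError(f"stage {stage!r} failed: {exc}") from exc

    manifest = {
        "chromkit_version": __version__,
        "seed": config.seed,
        "thresholds": {
            "q_strong": config.q_strong, "q_weak": config.q_weak,
            "promoter_halfwidth": config.promoter_halfwidth,
            "distal_min": config.distal_min, "distal_max": config.distal_max,
            "fdr_max": config.fdr_max, "min_fold": config.min_fold,
        },
        "reference_group": config.reference_group,
        "inputs": {
            "annotation": config.annotation,
            "peak_replicates": list(config.peak_replicates),
            "counts": config.counts,
            "sample_sheet": config.sample_sheet,
        },
        "n_final_peaks": len(final_peaks),
        "n_bound_genes": len(bound),
        "n_up": len(up),
        "n_down": len(down),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return {
        "final_peaks": final_peaks,
        "bound_genes": bound,
        "differential": results,
        "up": up,
        "down": down,
        "overlap_reports": reports,
        "overlap_table": table,
        "manifest": manifest,
    }
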