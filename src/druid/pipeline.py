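"""End-to-end orchestration: filter -> normalize -> fit, with run metadata.

The in-memory entry point is :func:`run_from_matrices`; :func:`run_pipeline`
is its file-based wrapper (TSV matrices in, TSV tables plus
``run_metadata.json`` out) used by the CLI. Every stage is a pure function
over its declared inputs, so any downstream stage can be resumed from the
files on disk.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .design import ExperimentDesign
from .fit import fit_table, write_half_lives
from .matrix import EXON_COUNT, INTRON_COVERAGE, AbundanceMatrix, GenomePartition
from .normalize import (
    IntronClusterReport,
    NormalizedSeries,
    cluster_and_select_introns,
    filter_genes,
    filter_introns,
    intron_normalization_factors,
    normalize,
    spikein_normalization_factors,
)


class PipelineError(RuntimeError):
    """A stage failure, naming the stage that raised it."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


@dataclass
class PipelineResult:
    half_lives: pd.DataFrame
    series: NormalizedSeries
    factors: pd.Series
    cluster_report: IntronClusterReport | None
    stage_counts: dict[str, int]
    design: ExperimentDesign


def _stage(name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as e:  # noqa: BLE001 — re-raised with the stage named
        raise PipelineError(name, e) from e


def run_from_matrices(
    design: ExperimentDesign,
    exon_counts: AbundanceMatrix,
    intron_coverage: AbundanceMatrix | None = None,
    partition: GenomePartition | None = None,
) -> PipelineResult:
    """Run filter -> normalize -> fit on precomputed abundance matrices.

    Intron mode requires ``intron_coverage``; spike-in mode requires
    ``partition``. In intron mode no growth correction is applied (gamma=0);
    in spike-in mode gamma = ln(2)/doubling_time.
    """
    counts: dict[str, int] = {"genes_input": len(exon_counts.feature_ids)}

    filtered = _stage(
        "filter_genes",
        filter_genes,
        exon_counts,
        design.gene_filter_min_all,
        design.gene_filter_min_any,
    )
    counts["genes_after_filter"] = len(filtered.feature_ids)

    report: IntronClusterReport | None = None
    if design.normalization_mode == "intron":
        if intron_coverage is None:
            raise PipelineError("normalize", ValueError("intron mode requires intron coverage"))
        counts["introns_input"] = len(intron_coverage.feature_ids)
        kept = _stage("filter_introns", filter_introns, intron_coverage, design.intron_min_coverage)
        counts["introns_after_filter"] = len(kept.feature_ids)
        report = _stage(
            "cluster_and_select_introns",
            cluster_and_select_introns,
            kept,
            design.kmeans_k,
            design.seed,
            select_cluster=design.select_cluster,
        )
        counts["introns_selected"] = len(report.selected_introns)
        factors = _stage(
            "intron_normalization_factors",
            intron_normalization_factors,
            kept,
            report.selected_introns,
        )
    elif design.normalization_mode == "spikein":
        if partition is None:
            raise PipelineError("normalize", ValueError("spikein mode requires a genome partition"))
        factors = _stage(
            "spikein_normalization_factors",
            spikein_normalization_factors,
            partition,
            design.spikein_labeled_label,
            design.min_spikein_reads,
        )
    else:  # "none": unit factors
        factors = pd.Series(1.0, index=list(exon_counts.data.columns), name="factor")

    series = _stage("normalize", normalize, filtered, factors, design.normalization_mode)
    table = _stage(
        "fit",
        fit_table,
        series,
        gamma=design.gamma,
        model=design.model,
        weights_scheme=design.weights_scheme,
    )
    counts["genes_converged"] = int(table["converged"].sum())
    return PipelineResult(table, series, factors, report, counts, design)


def ablate_time_points(
    design: ExperimentDesign,
    keep,
    exon_counts: AbundanceMatrix,
    intron_coverage: AbundanceMatrix | None = None,
    partition: GenomePartition | None = None,
) -> PipelineResult:
    """Re-run normalization and fitting restricted to a subset of time points
    (e.g. the minimal 1/8/24-h design). ``keep`` must be a subset of the
    design's time points with at least 3 members."""
    keep = sorted(float(t) for t in keep)
    if len(keep) < 3:
        raise ValueError(f"need >=3 time points, got {len(keep)}")
    if not set(keep) <= set(design.time_points):
        raise ValueError(f"{set(keep) - set(design.time_points)} not in design time points")
    sub_design = design.replace(time_points=tuple(keep))
    exon = exon_counts.subset_times(keep)
    intron = intron_coverage.subset_times(keep) if intron_coverage is not None else None
    part = (
        GenomePartition(partition.totals[keep]) if partition is not None else None
    )
    return run_from_matrices(sub_design, exon, intron, part)


def run_pipeline(
    design: ExperimentDesign,
    exon_counts_path: str | Path,
    intron_coverage_path: str | Path | None = None,
    genome_totals_path: str | Path | None = None,
    outdir: str | Path = ".",
) -> PipelineResult:
    """File-based pipeline: read TSV matrices, run, write all reports.

    Outputs under ``outdir``: half_lives.tsv, normalization_factors.tsv,
    introns_selected.tsv + cluster_centroids.tsv (intron mode), and
    run_metadata.json. Partial outputs are removed if a stage fails.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    exon = AbundanceMatrix.from_tsv(exon_counts_path, kind=EXON_COUNT)
    intron = (
        AbundanceMatrix.from_tsv(intron_coverage_path, kind=INTRON_COVERAGE)
        if intron_coverage_path
        else None
    )
    partition = GenomePartition.from_tsv(genome_totals_path) if genome_totals_path else None

    written: list[Path] = []
    try:
        result = run_from_matrices(design, exon, intron, partition)
        hl_path = outdir / "half_lives.tsv"
        write_half_lives(result.half_lives, hl_path)
        written.append(hl_path)
        fac_path = outdir / "normalization_factors.tsv"
        result.factors.rename_axis("time_hours").to_csv(fac_path, sep="\t")
        written.append(fac_path)
        if result.cluster_report is not None:
            sel_path = outdir / "introns_selected.tsv"
            cen_path = outdir / "cluster_centroids.tsv"
            result.cluster_report.to_tsv(sel_path, cen_path)
            written += [sel_path, cen_path]
        meta = {
            "druid_version": __version__,
            "config": design.to_dict(),
            "config_hash": design.config_hash(),
            "seed": design.seed,
            "stage_counts": result.stage_counts,
        }
        meta_path = outdir / "run_metadata.json"
        meta_path.write_text(json.dumps(meta, indent=2, default=str))
        written.append(meta_path)
        return result
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise
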