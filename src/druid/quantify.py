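"""Read-level quantification against the feature model.

Three measurements are produced per time point: gene-level exon read counts
(union counting, ambiguous reads discarded), intron-level mean per-base
coverage (finer-grained than counts for short features), and per-genome read
totals for merged multi-organism references (spike-in designs).

Spliced placements carry one aligned block per exon segment; each block is
treated independently for overlap and coverage so junction reads never
inflate intron signal.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .annotation import FeatureModel
from .intervals import GenomicInterval

UNASSIGNED = "unassigned"
AMBIGUOUS = "__ambiguous__"
NO_FEATURE = "__no_feature__"

STRANDEDNESS = ("reverse", "forward", "unstranded")


@dataclass
class Placement:
    """One aligned read: chromosome, strand, and aligned blocks (0-based,
    half-open, sorted, non-overlapping)."""

    chrom: str
    strand: str
    blocks: list[tuple[int, int]]

    def __post_init__(self) -> None:
        for s, e in self.blocks:
            if not (0 <= s < e):
                raise ValueError(f"invalid block [{s},{e}) on {self.chrom}")


def _strand_compatible(read_strand: str, feature_strand: str, strandedness: str) -> bool:
    if strandedness == "unstranded":
        return True
    if strandedness == "forward":
        return read_strand == feature_strand
    if strandedness == "reverse":
        return read_strand != feature_strand
    raise ValueError(f"strandedness must be one of {STRANDEDNESS}")


def read_placements_tsv(path: str | Path) -> list[Placement]:
    """Read placements from a TSV with columns read_id, chrom, start, end,
    strand; rows sharing a read_id are the aligned blocks of one read."""
    df = pd.read_csv(path, sep="\t", dtype={"read_id": str, "chrom": str})
    out = []
    for _, grp in df.groupby("read_id", sort=False):
        chrom = grp["chrom"].iloc[0]
        strand = grp["strand"].iloc[0]
        blocks = sorted(zip(grp["start"].astype(int), grp["end"].astype(int)))
        out.append(Placement(chrom=chrom, strand=strand, blocks=blocks))
    return out


def read_placements_bam(path: str | Path, min_mapq: int = 0) -> list[Placement]:
    """Read placements from a coordinate-sorted BAM via pysam; spliced
    alignments contribute their aligned blocks."""
    import pysam

    out = []
    with pysam.AlignmentFile(str(path)) as bam:
        for aln in bam.fetch(until_eof=True):
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            if aln.mapping_quality < min_mapq:
                continue
            blocks = aln.get_blocks()
            if not blocks:
                continue
            out.append(
                Placement(
                    chrom=aln.reference_name,
                    strand="-" if aln.is_reverse else "+",
                    blocks=[(int(s), int(e)) for s, e in blocks],
                )
            )
    return out


def _exon_trees(model: FeatureModel) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = collections.defaultdict(IntervalTree)
    for gene_id, _, iv in model.all_exons():
        trees[iv.chrom].addi(iv.start, iv.end, (gene_id, iv.strand))
    return trees


def count_exon_reads(
    placements: Sequence[Placement],
    model: FeatureModel,
    strandedness: str = "reverse",
) -> pd.Series:
    """Union-count reads per gene for one time point.

    A read increments a gene iff at least one of its blocks overlaps an exon
    of that gene's chosen transcript and it overlaps no other gene's exons;
    reads hitting two or more genes are discarded as ambiguous. Reads on
    chromosomes absent from the model fall in the ``unassigned`` bucket.
    Returns a Series over every model gene plus the ``unassigned``,
    ``__ambiguous__`` and ``__no_feature__`` buckets.
    """
    trees = _exon_trees(model)
    counts = {g: 0 for g in model.genes}
    counts[UNASSIGNED] = 0
    counts[AMBIGUOUS] = 0
    counts[NO_FEATURE] = 0
    for read in placements:
        tree = trees.get(read.chrom)
        if tree is None:
            counts[UNASSIGNED] += 1
            continue
        hits: set[str] = set()
        for s, e in read.blocks:
            for hit in tree.overlap(s, e):
                gene_id, feat_strand = hit.data
                if _strand_compatible(read.strand, feat_strand, strandedness):
                    hits.add(gene_id)
        if len(hits) == 1:
            counts[hits.pop()] += 1
        elif len(hits) > 1:
            counts[AMBIGUOUS] += 1
        else:
            counts[NO_FEATURE] += 1
    return pd.Series(counts, dtype=float)


def intron_mean_coverage(
    placements: Sequence[Placement],
    model: FeatureModel,
    strandedness: str = "reverse",
) -> pd.Series:
    """Mean per-base depth over each retained intron for one time point.

    Depth is accumulated at nucleotide resolution across the intron's
    ``[start, end)`` span and averaged over its length; reads need not be
    intron-exclusive. Index keys are ``gene_id|intron_index``.
    """
    introns = model.all_introns()
    tree_by_chrom: dict[str, IntervalTree] = collections.defaultdict(IntervalTree)
    depth: dict[str, np.ndarray] = {}
    meta: dict[str, GenomicInterval] = {}
    for gene_id, idx, iv in introns:
        key = f"{gene_id}|{idx}"
        tree_by_chrom[iv.chrom].addi(iv.start, iv.end, key)
        depth[key] = np.zeros(len(iv), dtype=float)
        meta[key] = iv
    for read in placements:
        tree = tree_by_chrom.get(read.chrom)
        if tree is None:
            continue
        for s, e in read.blocks:
            for hit in tree.overlap(s, e):
                key = hit.data
                iv = meta[key]
                if not _strand_compatible(read.strand, iv.strand, strandedness):
                    continue
                lo = max(s, iv.start) - iv.start
                hi = min(e, iv.end) - iv.start
                depth[key][lo:hi] += 1.0
    return pd.Series({k: float(v.mean()) for k, v in depth.items()}, dtype=float)


def label_for_chrom(chrom: str, genome_label_map: Mapping[str, str]) -> str:
    """Resolve a chromosome to its genome label: exact match first, then the
    ``label_`` prefix convention of merged references, else ``unassigned``."""
    if chrom in genome_label_map:
        return genome_label_map[chrom]
    for prefix, label in genome_label_map.items():
        if chrom.startswith(prefix + "_") or chrom.startswith(prefix):
            return label
    return UNASSIGNED


def partition_by_genome(
    placements: Sequence[Placement],
    genome_label_map: Mapping[str, str],
) -> pd.Series:
    """Total placements per genome label for one time point (plus an
    ``unassigned`` bucket for unknown chromosomes). The totals sum to the
    number of placements."""
    labels = sorted(set(genome_label_map.values())) + [UNASSIGNED]
    totals = {lbl: 0 for lbl in labels}
    for read in placements:
        totals[label_for_chrom(read.chrom, genome_label_map)] += 1
    return pd.Series(totals, dtype=float)


def write_bedgraph(
    depth_by_interval: Mapping[str, tuple[GenomicInterval, np.ndarray]],
    path: str | Path,
) -> None:
    """Optional diagnostic export of per-base depth as bedGraph runs."""
    with open(path, "w") as fh:
        for _, (iv, depth) in depth_by_interval.items():
            run_start = 0
            for i in range(1, len(depth) + 1):
                if i == len(depth) or depth[i] != depth[run_start]:
                    if depth[run_start] != 0:
                        fh.write(
                            f"{iv.chrom}\t{iv.start + run_start}\t{iv.start + i}\t"
                            f"{depth[run_start]:g}\n"
                        )
                    run_start = i
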