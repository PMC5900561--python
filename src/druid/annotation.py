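"""Exon/intron feature model built from a genome annotation.

One representative transcript is chosen per gene — the one with the largest
summed exon length — and introns are the gaps between its consecutive exons.
Because reads from mature mRNA must never be mistaken for intronic signal,
any intron that overlaps an exon of *any* isoform (by default of any gene on
the same chromosome, either strand) is removed before quantification.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from .intervals import GenomicInterval


@dataclass
class TranscriptRecord:
    """A flat annotation record: one transcript with its exons."""

    gene_id: str
    transcript_id: str
    exons: list[GenomicInterval]


@dataclass
class GeneModel:
    """The chosen transcript of one gene with its exons and retained introns."""

    gene_id: str
    transcript_id: str
    exons: list[GenomicInterval]
    introns: list[GenomicInterval]
    genome_label: str = ""


@dataclass
class FeatureModel:
    """Per-gene exon/intron intervals for the single chosen transcript.

    ``genes`` maps gene_id -> :class:`GeneModel`. Within a gene the exons are
    sorted and non-overlapping; introns are exactly the inter-exon gaps that
    survived the isoform-exon overlap filter.
    """

    genes: dict[str, GeneModel] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.genes)

    def all_exons(self) -> list[tuple[str, int, GenomicInterval]]:
        return [
            (g.gene_id, i, iv)
            for g in self.genes.values()
            for i, iv in enumerate(g.exons)
        ]

    def all_introns(self) -> list[tuple[str, int, GenomicInterval]]:
        return [
            (g.gene_id, i, iv)
            for g in self.genes.values()
            for i, iv in enumerate(g.introns)
        ]


def _merge_sorted(exons: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Sort exons and merge any that touch or overlap (defensive against
    annotations listing overlapping exon parts)."""
    out: list[GenomicInterval] = []
    for iv in sorted(exons, key=lambda e: (e.start, e.end)):
        if out and iv.start <= out[-1].end:
            prev = out[-1]
            if iv.end > prev.end:
                out[-1] = GenomicInterval(prev.chrom, prev.start, iv.end, prev.strand)
        else:
            out.append(iv)
    return out


def introns_between(exons: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Gaps between consecutive (sorted, merged) exons of one transcript."""
    merged = _merge_sorted(exons)
    gaps = []
    for left, right in zip(merged, merged[1:]):
        if right.start > left.end:
            gaps.append(GenomicInterval(left.chrom, left.end, right.start, left.strand))
    return gaps


def select_longest_transcript(
    records: Iterable[TranscriptRecord],
    genome_labels: Mapping[str, str] | None = None,
) -> FeatureModel:
    """Choose, per gene, the transcript with maximal summed exon length.

    Ties break to the lexicographically smallest transcript_id so builds are
    deterministic. Introns are derived as inter-exon gaps; single-exon genes
    get an empty intron list. Malformed records (no exons, exons on multiple
    chromosomes) are rejected with the offending transcript named.
    """
    best: dict[str, tuple[int, str, TranscriptRecord]] = {}
    for rec in records:
        if not rec.exons:
            raise ValueError(f"transcript {rec.transcript_id}: no exons")
        chroms = {e.chrom for e in rec.exons}
        if len(chroms) > 1:
            raise ValueError(
                f"transcript {rec.transcript_id}: exons on multiple chromosomes {sorted(chroms)}"
            )
        length = sum(len(e) for e in rec.exons)
        key = (-length, rec.transcript_id)
        cur = best.get(rec.gene_id)
        if cur is None or key < (-cur[0], cur[1]):
            best[rec.gene_id] = (length, rec.transcript_id, rec)

    model = FeatureModel()
    for gene_id, (_, tid, rec) in sorted(best.items()):
        exons = _merge_sorted(rec.exons)
        model.genes[gene_id] = GeneModel(
            gene_id=gene_id,
            transcript_id=tid,
            exons=exons,
            introns=introns_between(exons),
            genome_label=(genome_labels or {}).get(gene_id, ""),
        )
    return model


def filter_introns_by_exon_overlap(
    model: FeatureModel,
    all_isoform_exons: Iterable[GenomicInterval],
    same_gene_only: bool = False,
) -> FeatureModel:
    """Drop every intron that shares >=1 base with any isoform exon.

    ``all_isoform_exons`` should cover every isoform of every gene. Overlap is
    strand-agnostic (half-open coordinates: abutting intervals do not
    overlap). With ``same_gene_only`` the caller restricts the exon list
    themselves; the operation is a pure interval filter and is idempotent.
    """
    trees: dict[str, IntervalTree] = collections.defaultdict(IntervalTree)
    for ex in all_isoform_exons:
        trees[ex.chrom].addi(ex.start, ex.end)

    out = FeatureModel()
    for gene_id, gm in model.genes.items():
        kept = [
            iv
            for iv in gm.introns
            if not trees.get(iv.chrom) or not trees[iv.chrom].overlap(iv.start, iv.end)
        ]
        out.genes[gene_id] = GeneModel(
            gene_id=gm.gene_id,
            transcript_id=gm.transcript_id,
            exons=list(gm.exons),
            introns=kept,
            genome_label=gm.genome_label,
        )
    return out


# ---------------------------------------------------------------------------
# GTF input / BED6 output


def read_gtf(path: str | Path) -> tuple[list[TranscriptRecord], list[GenomicInterval]]:
    """Parse a GTF file into transcript records plus the full isoform exon list.

    Uses gffutils with an in-memory database; requires ``gene_id`` and
    ``transcript_id`` attributes on exon features (Ensembl/UCSC dialects).
    GTF 1-based closed coordinates are converted to 0-based half-open.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    by_tx: dict[str, TranscriptRecord] = {}
    all_exons: list[GenomicInterval] = []
    for ex in db.features_of_type("exon"):
        try:
            gene_id = ex.attributes["gene_id"][0]
            tx_id = ex.attributes["transcript_id"][0]
        except KeyError as e:
            raise ValueError(f"exon at {ex.seqid}:{ex.start}-{ex.end} lacks {e} attribute")
        iv = GenomicInterval(ex.seqid, ex.start - 1, ex.end, ex.strand if ex.strand in "+-" else "+")
        all_exons.append(iv)
        rec = by_tx.setdefault(tx_id, TranscriptRecord(gene_id, tx_id, []))
        rec.exons.append(iv)
    return list(by_tx.values()), all_exons


def build_feature_model(
    gtf_path: str | Path,
    genome_labels: Mapping[str, str] | None = None,
    filter_other_isoform_exons: bool = True,
) -> FeatureModel:
    """GTF -> longest-transcript model -> intron/exon-overlap filter."""
    records, all_exons = read_gtf(gtf_path)
    model = select_longest_transcript(records, genome_labels=genome_labels)
    if filter_other_isoform_exons:
        model = filter_introns_by_exon_overlap(model, all_exons)
    return model


def write_bed6(model: FeatureModel, exons_path: str | Path, introns_path: str | Path) -> None:
    """Write the feature model as BED6 (name = gene_id|feature_index)."""

    def _write(path: str | Path, features: list[tuple[str, int, GenomicInterval]]) -> None:
        with open(path, "w") as fh:
            for gene_id, idx, iv in features:
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{gene_id}|{idx}\t0\t{iv.strand}\n"
                )

    _write(exons_path, model.all_exons())
    _write(introns_path, model.all_introns())
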