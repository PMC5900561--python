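import numpy as np
import pandas as pd
import pytest

from druid.annotation import FeatureModel, GeneModel
from druid.intervals import GenomicInterval


@pytest.fixture
def toy_model() -> FeatureModel:
    """Two genes on chr1: gA (+) with one retained intron, gB (-) with one."""
    model = FeatureModel()
    model.genes["gA"] = GeneModel(
        gene_id="gA",
        transcript_id="gA.1",
        exons=[
            GenomicInterval("chr1", 100, 200, "+"),
            GenomicInterval("chr1", 300, 400, "+"),
            GenomicInterval("chr1", 500, 600, "+"),
        ],
        introns=[GenomicInterval("chr1", 400, 500, "+")],
    )
    model.genes["gB"] = GeneModel(
        gene_id="gB",
        transcript_id="gB.1",
        exons=[
            GenomicInterval("chr1", 1000, 1100, "-"),
            GenomicInterval("chr1", 1300, 1400, "-"),
        ],
        introns=[GenomicInterval("chr1", 1100, 1300, "-")],
    )
    return model


@pytest.fixture
def toy_gtf(tmp_path):
    """GTF with a two-isoform gene (longest 300 nt exonic) and a single-isoform
    gene; isoform gA.2's first exon overlaps gA.1's first intron."""
    lines = [
        'chr1\tt\texon\t101\t200\t.\t+\t.\tgene_id "gA"; transcript_id "gA.1";',
        'chr1\tt\texon\t301\t400\t.\t+\t.\tgene_id "gA"; transcript_id "gA.1";',
        'chr1\tt\texon\t501\t600\t.\t+\t.\tgene_id "gA"; transcript_id "gA.1";',
        'chr1\tt\texon\t101\t250\t.\t+\t.\tgene_id "gA"; transcript_id "gA.2";',
        'chr1\tt\texon\t301\t400\t.\t+\t.\tgene_id "gA"; transcript_id "gA.2";',
        'chr1\tt\texon\t1001\t1100\t.\t-\t.\tgene_id "gB"; transcript_id "gB.1";',
        'chr1\tt\texon\t1301\t1400\t.\t-\t.\tgene_id "gB"; transcript_id "gB.1";',
    ]
    path = tmp_path / "toy.gtf"
    path.write_text("\n".join(lines) + "\n")
    return path


TIME_POINTS = (1.0, 2.0, 4.0, 8.0, 12.0, 24.0)


def bounded_growth(t, n0, lam, gamma=0.0):
    t = np.asarray(t, dtype=float)
    return n0 * (1.0 - np.exp(-(lam + gamma) * t))
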