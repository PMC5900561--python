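"""From a GTF annotation to exon counts and intron coverage.

Builds the longest-transcript feature model (introns purged of any isoform
exon overlap), then quantifies a handful of read placements against it.
"""

import tempfile
from pathlib import Path

from druid.annotation import build_feature_model
from druid.quantify import Placement, count_exon_reads, intron_mean_coverage

GTF = """\
chr1\tdemo\texon\t101\t200\t.\t+\t.\tgene_id "gA"; transcript_id "gA.1";
chr1\tdemo\texon\t301\t400\t.\t+\t.\tgene_id "gA"; transcript_id "gA.1";
chr1\tdemo\texon\t501\t600\t.\t+\t.\tgene_id "gA"; transcript_id "gA.1";
chr1\tdemo\texon\t101\t250\t.\t+\t.\tgene_id "gA"; transcript_id "gA.2";
chr1\tdemo\texon\t1001\t1100\t.\t-\t.\tgene_id "gB"; transcript_id "gB.1";
chr1\tdemo\texon\t1301\t1400\t.\t-\t.\tgene_id "gB"; transcript_id "gB.1";
"""

with tempfile.TemporaryDirectory() as tmp:
    gtf = Path(tmp) / "demo.gtf"
    gtf.write_text(GTF)
    model = build_feature_model(gtf)

for gene_id, gm in model.genes.items():
    print(gene_id, gm.transcript_id,
          "exons", [(e.start, e.end) for e in gm.exons],
          "introns", [(i.start, i.end) for i in gm.introns])
# gA keeps only its second intron: the first one overlaps isoform gA.2's exon.

reads = [
    Placement("chr1", "-", [(150, 160)]),            # exonic in gA (reverse library)
    Placement("chr1", "-", [(390, 400), (500, 510)]),  # junction read, blocks in exons
    Placement("chr1", "-", [(420, 470)]),            # 50 nt inside gA's 100-nt intron
    Placement("chr1", "+", [(1010, 1060)]),          # exonic in gB
]
print("exon counts:", dict(count_exon_reads(reads, model).loc[["gA", "gB"]]))
print("intron mean coverage:", dict(intron_mean_coverage(reads, model)))
# the junction read counts for gA but adds no intron coverage: aligned
# blocks, not the spliced-over gap, carry the signal.
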