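"""Feature-model construction: longest-transcript choice, intron derivation,
and the isoform-exon overlap filter, checked against brute-force oracles."""

import numpy as np
import pytest

from druid.annotation import (
    TranscriptRecord,
    build_feature_model,
    filter_introns_by_exon_overlap,
    introns_between,
    select_longest_transcript,
    write_bed6,
)
from druid.intervals import GenomicInterval


def iv(start, end, chrom="chr1", strand="+"):
    return GenomicInterval(chrom, start, end, strand)


class TestGenomicInterval:
    def test_rejects_malformed(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 10, 10)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -1, 5)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 0, 5, ".")

    def test_half_open_overlap(self):
        assert iv(200, 300).overlaps(iv(250, 350))
        assert not iv(200, 300).overlaps(iv(300, 400))  # abutting: no shared base
        assert not iv(200, 300).overlaps(iv(250, 350, chrom="chr2"))


class TestSelectLongestTranscript:
    def test_picks_maximal_exonic_length(self):
        recs = [
            TranscriptRecord("g", "t300", [iv(0, 300)]),
            TranscriptRecord("g", "t500", [iv(1000, 1500)]),
        ]
        model = select_longest_transcript(recs)
        assert model.genes["g"].transcript_id == "t500"

    def test_tie_breaks_to_smallest_transcript_id(self):
        recs = [
            TranscriptRecord("g", "tB", [iv(0, 100)]),
            TranscriptRecord("g", "tA", [iv(500, 600)]),
        ]
        assert select_longest_transcript(recs).genes["g"].transcript_id == "tA"

    def test_single_exon_gene_has_no_introns(self):
        model = select_longest_transcript([TranscriptRecord("g", "t", [iv(0, 100)])])
        assert model.genes["g"].introns == []

    def test_introns_are_inter_exon_gaps(self):
        exons = [iv(100, 200), iv(300, 400), iv(500, 600)]
        model = select_longest_transcript([TranscriptRecord("g", "t", exons)])
        got = [(i.start, i.end) for i in model.genes["g"].introns]
        assert got == [(200, 300), (400, 500)]

    def test_rejects_transcript_without_exons(self):
        with pytest.raises(ValueError, match="tX"):
            select_longest_transcript([TranscriptRecord("g", "tX", [])])


class TestFilterIntronsByExonOverlap:
    def _one_intron_model(self):
        return select_longest_transcript(
            [TranscriptRecord("g", "t", [iv(100, 200), iv(300, 400)])]
        )

    def test_overlapping_intron_removed(self):
        model = filter_introns_by_exon_overlap(self._one_intron_model(), [iv(250, 350)])
        assert model.genes["g"].introns == []

    def test_abutting_exon_keeps_intron(self):
        model = filter_introns_by_exon_overlap(self._one_intron_model(), [iv(300, 400)])
        assert len(model.genes["g"].introns) == 1

    def test_empty_exon_list_is_noop_and_idempotent(self):
        base = self._one_intron_model()
        once = filter_introns_by_exon_overlap(base, [])
        assert [i.start for i in once.genes["g"].introns] == [200]
        exons = [iv(250, 350)]
        f1 = filter_introns_by_exon_overlap(base, exons)
        f2 = filter_introns_by_exon_overlap(f1, exons)
        assert {g: [(i.start, i.end) for i in gm.introns] for g, gm in f1.genes.items()} == {
            g: [(i.start, i.end) for i in gm.introns] for g, gm in f2.genes.items()
        }

    def test_five_introns_two_overlapped(self):
        exons = [iv(100 * i, 100 * i + 50) for i in range(0, 12, 2)]  # 6 exons, 5 gaps
        model = select_longest_transcript([TranscriptRecord("g", "t", exons)])
        assert len(model.genes["g"].introns) == 5
        isoform_exons = [iv(60, 80), iv(260, 270)]  # hit introns 0 and 1
        filtered = filter_introns_by_exon_overlap(model, isoform_exons)
        assert len(filtered.genes["g"].introns) == 3

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            n_ex = rng.integers(3, 10)
            starts = np.sort(rng.choice(np.arange(0, 5000, 10), size=n_ex, replace=False))
            exons = [iv(int(s), int(s + rng.integers(10, 100))) for s in starts]
            model = select_longest_transcript([TranscriptRecord("g", "t", exons)])
            others = [
                iv(int(s), int(s + rng.integers(5, 200)))
                for s in rng.choice(np.arange(0, 5500, 7), size=15, replace=False)
            ]
            filtered = filter_introns_by_exon_overlap(model, others)
            expect = [
                intr
                for intr in model.genes["g"].introns
                if not any(intr.overlaps(e) for e in others)
            ]
            assert filtered.genes["g"].introns == expect

    def test_retained_introns_abut_chosen_exons(self):
        rng = np.random.default_rng(7)
        starts = np.sort(rng.choice(np.arange(0, 3000, 10), size=6, replace=False))
        exons = [iv(int(s), int(s + 8)) for s in starts]
        model = select_longest_transcript([TranscriptRecord("g", "t", exons)])
        gm = model.genes["g"]
        span = (gm.exons[0].start, gm.exons[-1].end)
        bounds = {e.start for e in gm.exons} | {e.end for e in gm.exons}
        for intr in gm.introns:
            assert span[0] < intr.start < intr.end < span[1]
            assert intr.start in bounds and intr.end in bounds


class TestGtfRoundTrip:
    def test_build_feature_model(self, toy_gtf):
        model = build_feature_model(toy_gtf)
        ga = model.genes["gA"]
        assert ga.transcript_id == "gA.1"  # 300 nt beats gA.2's 250 nt
        # first intron [200,300) overlaps gA.2's exon [100,250) -> removed
        assert [(i.start, i.end) for i in ga.introns] == [(400, 500)]
        assert [(i.start, i.end) for i in model.genes["gB"].introns] == [(1100, 1300)]

    def test_write_bed6(self, toy_gtf, tmp_path):
        model = build_feature_model(toy_gtf)
        write_bed6(model, tmp_path / "exons.bed", tmp_path / "introns.bed")
        lines = (tmp_path / "introns.bed").read_text().strip().split("\n")
        fields = lines[0].split("\t")
        assert fields[0] == "chr1" and fields[3] == "gA|0" and fields[5] == "+"
        assert (int(fields[1]), int(fields[2])) == (400, 500)


def test_introns_between_merges_overlapping_exons():
    exons = [iv(0, 100), iv(50, 150), iv(300, 400)]
    assert [(g.start, g.end) for g in introns_between(exons)] == [(150, 300)]
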