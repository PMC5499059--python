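import random

import pytest

from strandqc.annotation import (
    AnnotationIndex,
    Junction,
    TranscriptModel,
    classify_interval_set,
    fragment_strand,
    junctions_spanned,
    parse_gtf,
    write_gtf,
)
from strandqc.errors import ValidationError
from strandqc.io_model import (
    FLAG_PAIRED,
    FLAG_READ1,
    FLAG_READ2,
    FLAG_REVERSE,
)

from conftest import make_record


class TestJunctionExtraction:
    def test_two_exon_transcript_yields_one_junction(self):
        tx = TranscriptModel("t1", "g1", "chr1", "+", ((100, 200), (300, 400)))
        index = AnnotationIndex([tx])
        assert index.junctions == {Junction("chr1", 200, 300, "+")}

    def test_shared_junction_deduplicated_across_transcripts(self):
        t1 = TranscriptModel("t1", "g1", "chr1", "+", ((100, 200), (300, 400)))
        t2 = TranscriptModel("t2", "g1", "chr1", "+", ((50, 200), (300, 450)))
        index = AnnotationIndex([t1, t2])
        assert len(index.junctions) == 1

    def test_adjacent_pairs_enumerated_per_transcript(self):
        # 2, 3 and 1 exons -> 1 + 2 + 0 = 3 distinct junctions
        txs = [
            TranscriptModel("t1", "g1", "chr1", "+", ((100, 200), (300, 400))),
            TranscriptModel(
                "t2", "g2", "chr1", "+", ((1000, 1100), (1200, 1300), (1400, 1500))
            ),
            TranscriptModel("t3", "g3", "chr1", "-", ((2000, 2500),)),
        ]
        index = AnnotationIndex(txs)
        assert index.junctions == {
            Junction("chr1", 200, 300, "+"),
            Junction("chr1", 1100, 1200, "+"),
            Junction("chr1", 1300, 1400, "+"),
        }

    def test_extraction_independent_of_transcript_order(self, toy_transcripts):
        shuffled = list(toy_transcripts)
        random.Random(7).shuffle(shuffled)
        assert (
            AnnotationIndex(shuffled).junctions
            == AnnotationIndex(toy_transcripts).junctions
        )


class TestGtfParsing:
    def test_round_trip_through_gtf(self, tmp_path, toy_transcripts):
        path = tmp_path / "a.gtf"
        write_gtf(toy_transcripts, path)
        index = parse_gtf(path)
        assert set(index.transcripts) == {t.transcript_id for t in toy_transcripts}
        assert index.transcripts["TXA.1"].exons == ((100, 300), (500, 700), (900, 1100))
        assert index.rrna_genes == {"GENER"}
        assert index.mito_contig == "chrM"
        assert index.junctions == AnnotationIndex(toy_transcripts).junctions

    def test_invalid_exon_rejected(self, tmp_path):
        path = tmp_path / "bad.gtf"
        path.write_text(
            'chr1\tx\texon\t500\t100\t.\t+\t.\tgene_id "g"; transcript_id "t";\n'
        )
        with pytest.raises(ValidationError):
            parse_gtf(path)

    def test_transcript_on_two_contigs_rejected(self, tmp_path):
        path = tmp_path / "bad.gtf"
        path.write_text(
            'chr1\tx\texon\t100\t200\t.\t+\t.\tgene_id "g"; transcript_id "t";\n'
            'chr2\tx\texon\t300\t400\t.\t+\t.\tgene_id "g"; transcript_id "t";\n'
        )
        with pytest.raises(ValidationError):
            parse_gtf(path)


class TestClassification:
    def test_read_inside_exon_is_exonic(self, toy_index):
        assert classify_interval_set([("chr1", 120, 195)], toy_index) == "exonic"

    def test_read_in_intron_is_intronic(self, toy_index):
        assert classify_interval_set([("chr1", 320, 395)], toy_index) == "intronic"

    def test_read_outside_genes_is_intergenic(self, toy_index):
        assert classify_interval_set([("chr1", 8000, 8075)], toy_index) == "intergenic"

    def test_majority_rule_with_exonic_precedence(self, toy_index):
        # 60 bases in exon [100,300), 40 in the following intron
        assert classify_interval_set([("chr1", 240, 340)], toy_index) == "exonic"
        # 40 exonic / 60 intronic -> intronic
        assert classify_interval_set([("chr1", 260, 360)], toy_index) == "intronic"

    def test_unknown_contig_is_lookup_error(self, toy_index):
        with pytest.raises(LookupError):
            classify_interval_set([("chr7", 0, 75)], toy_index)

    def test_gene_assignment_unique_and_ambiguous(self):
        t1 = TranscriptModel("t1", "g1", "chr1", "+", ((100, 300),))
        t2 = TranscriptModel("t2", "g2", "chr1", "+", ((250, 450),))
        index = AnnotationIndex([t1, t2])
        assert index.assign_gene([("chr1", 120, 195)]) == ("g1", False)
        assert index.assign_gene([("chr1", 230, 320)]) == (None, True)
        assert index.assign_gene([("chr1", 600, 675)]) == (None, False)


class TestJunctionSpanning:
    def test_exact_skip_matches_annotated_junction(self, toy_index):
        rec = make_record(
            "r", FLAG_PAIRED | FLAG_READ2, "chr1", 270, [("M", 30), ("N", 200), ("M", 45)]
        )
        hits = junctions_spanned(rec, toy_index, min_overhang=3, orientation="reverse")
        assert hits == [(Junction("chr1", 300, 500, "+"), True)]

    def test_read_without_skip_spans_nothing(self, toy_index):
        rec = make_record("r", 0, "chr1", 120, [("M", 75)])
        assert junctions_spanned(rec, toy_index) == []

    def test_short_overhang_rejected(self, toy_index):
        rec = make_record(
            "r", FLAG_PAIRED | FLAG_READ2, "chr1", 298, [("M", 2), ("N", 200), ("M", 73)]
        )
        assert junctions_spanned(rec, toy_index, min_overhang=3) == []
        assert len(junctions_spanned(rec, toy_index, min_overhang=1)) == 1

    def test_skip_not_matching_annotation_ignored(self, toy_index):
        rec = make_record(
            "r", FLAG_PAIRED | FLAG_READ2, "chr1", 271, [("M", 30), ("N", 199), ("M", 45)]
        )
        assert junctions_spanned(rec, toy_index) == []

    def test_antisense_read_flagged_as_antisense(self, toy_index):
        # read2 mapped forward on a + junction under dUTP chemistry = sense;
        # read1 mapped forward = antisense
        sense_rec = make_record(
            "r", FLAG_PAIRED | FLAG_READ2, "chr1", 270, [("M", 30), ("N", 200), ("M", 45)]
        )
        anti_rec = make_record(
            "r", FLAG_PAIRED | FLAG_READ1, "chr1", 270, [("M", 30), ("N", 200), ("M", 45)]
        )
        assert junctions_spanned(sense_rec, toy_index)[0][1] is True
        assert junctions_spanned(anti_rec, toy_index)[0][1] is False


class TestFragmentStrand:
    @pytest.mark.parametrize(
        "orientation,read_flag,reverse,expected",
        [
            ("reverse", FLAG_READ1, False, "-"),
            ("reverse", FLAG_READ1, True, "+"),
            ("reverse", FLAG_READ2, False, "+"),
            ("forward", FLAG_READ1, False, "+"),
            ("forward", FLAG_READ2, True, "+"),
        ],
    )
    def test_orientation_table(self, orientation, read_flag, reverse, expected):
        flags = FLAG_PAIRED | read_flag | (FLAG_REVERSE if reverse else 0)
        rec = make_record("r", flags, cigar=[("M", 75)])
        assert fragment_strand(rec, orientation) == expected

    def test_unstranded_returns_none(self):
        rec = make_record("r", FLAG_PAIRED | FLAG_READ1, cigar=[("M", 75)])
        assert fragment_strand(rec, "unstranded") is None


def test_simulated_spliced_reads_recover_their_junctions(small_simulation):
    """Every N-skip the simulator emits matches an annotated intron."""
    index = small_simulation["index"]
    n_spliced = 0
    for rec in small_simulation["records"]:
        if rec.is_unmapped or not rec.has_skip():
            continue
        n_spliced += 1
        n_skips = sum(1 for op, _ in rec.cigar if op == "N")
        hits = junctions_spanned(rec, index, min_overhang=1)
        assert len(hits) == n_skips
    assert n_spliced > 100  # the library genuinely exercises splicing
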