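import dataclasses

import pytest

from strandqc.annotation import AnnotationIndex, TranscriptModel
from strandqc.io_model import (
    FLAG_MATE_REVERSE,
    FLAG_PAIRED,
    FLAG_PROPER_PAIR,
    FLAG_READ1,
    FLAG_READ2,
    FLAG_REVERSE,
    FLAG_UNMAPPED,
    AlignmentRecord,
)
from strandqc.synthetic import SimulationConfig, generate_reference_and_annotation, simulate_library


def make_record(
    name="r1",
    flags=0,
    contig="chr1",
    pos=100,
    cigar=((("M", 75)),),
    mate_contig=None,
    mate_pos=None,
    tlen=0,
    seq=None,
    quals=None,
    mapq=60,
):
    """Terse hand-built alignment record for unit tests."""
    cigar = [tuple(c) for c in cigar] if not flags & FLAG_UNMAPPED else []
    qlen = sum(l for op, l in cigar if op in "MIS") if cigar else 75
    if seq is None:
        seq = "A" * qlen
    if quals is None:
        quals = [30] * len(seq)
    return AlignmentRecord(
        query_name=name,
        flags=flags,
        reference_name=None if flags & FLAG_UNMAPPED else contig,
        position=None if flags & FLAG_UNMAPPED else pos,
        mapping_quality=mapq,
        cigar=cigar,
        mate_reference_name=mate_contig,
        mate_position=mate_pos,
        template_length=tlen,
        sequence=seq,
        base_qualities=list(quals),
    )


def make_pair(name, contig, left_pos, right_pos, read_len=75, flen=None, quals=None):
    """A proper FR pair: forward read1 at left_pos, reverse read2 at right_pos."""
    if flen is None:
        flen = right_pos + read_len - left_pos
    r1 = make_record(
        name,
        FLAG_PAIRED | FLAG_PROPER_PAIR | FLAG_READ1 | FLAG_MATE_REVERSE,
        contig,
        left_pos,
        [("M", read_len)],
        mate_contig=contig,
        mate_pos=right_pos,
        tlen=flen,
        quals=quals,
    )
    r2 = make_record(
        name,
        FLAG_PAIRED | FLAG_PROPER_PAIR | FLAG_READ2 | FLAG_REVERSE,
        contig,
        right_pos,
        [("M", read_len)],
        mate_contig=contig,
        mate_pos=left_pos,
        tlen=-flen,
        quals=quals,
    )
    return [r1, r2]


@pytest.fixture(scope="session")
def toy_transcripts():
    """Two spliced genes (+/-), one rRNA gene, one mitochondrial gene."""
    return [
        TranscriptModel("TXA.1", "GENEA", "chr1", "+", ((100, 300), (500, 700), (900, 1100))),
        TranscriptModel("TXB.1", "GENEB", "chr1", "-", ((2000, 2300), (2800, 3100))),
        TranscriptModel("RRNA.1", "GENER", "chr1", "+", ((5000, 6500),), biotype="rRNA"),
        TranscriptModel("MITO.1", "GENEM", "chrM", "+", ((100, 2100),)),
    ]


@pytest.fixture(scope="session")
def toy_index(toy_transcripts):
    return AnnotationIndex(toy_transcripts, extra_contigs=["chr2"])


@pytest.fixture(scope="session")
def small_simulation():
    """One 2000-fragment library with every generative effect switched on."""
    config = SimulationConfig(
        seed=42,
        n_genes=80,
        n_fragments=2000,
        antisense_rate=0.05,
        substitution_rate=0.003,
        duplication_mean_extra=0.25,
        spikein_fraction=0.05,
    )
    reference, transcripts, panel = generate_reference_and_annotation(config)
    records, truth = simulate_library(config, reference, transcripts, panel)
    index = AnnotationIndex(transcripts, extra_contigs=reference.lengths)
    return {
        "config": config,
        "reference": reference,
        "transcripts": transcripts,
        "panel": panel,
        "records": records,
        "truth": truth,
        "index": index,
    }
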