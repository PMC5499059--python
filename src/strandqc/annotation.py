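"""Interval-indexed gene models and the annotated exon-exon junction set.

The junction set is the backbone of the strand-specificity statistic: a
read is credited with spanning a junction only when its N-skip matches an
annotated intron exactly at both coordinates, which avoids crediting
misaligned skips or genomic-DNA background.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Optional

import pandas as pd
from intervaltree import IntervalTree

from .errors import ParseError, ValidationError
from .io_model import AlignmentRecord

#: contig names recognised as mitochondrial when none is configured
MITO_NAMES = ("chrM", "MT", "chrMT", "M")

#: library orientations: how the strand of the originating RNA fragment is
#: inferred from read flags.  "reverse" is dUTP chemistry (first-in-pair
#: sequences antisense to the transcript), "forward" the opposite,
#: "unstranded" means no inference is possible.
ORIENTATIONS = ("reverse", "forward", "unstranded")


class Junction(NamedTuple):
    contig: str
    donor_end: int  # end of upstream exon, 0-based exclusive
    acceptor_start: int  # start of downstream exon
    strand: str


@dataclass(frozen=True)
class TranscriptModel:
    transcript_id: str
    gene_id: str
    contig: str
    strand: str
    exons: tuple[tuple[int, int], ...]  # 0-based half-open, sorted by start
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValidationError(f"{self.transcript_id}: transcript has no exons")
        prev_end = -1
        for start, end in self.exons:
            if end <= start:
                raise ValidationError(
                    f"{self.transcript_id}: exon [{start},{end}) is empty or inverted"
                )
            if start < prev_end:
                raise ValidationError(
                    f"{self.transcript_id}: exons overlap or are unsorted"
                )
            prev_end = end
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.transcript_id}: bad strand {self.strand!r}")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def length(self) -> int:
        """Spliced (exonic) length."""
        return sum(e - s for s, e in self.exons)

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        ]

    def junctions(self) -> list[Junction]:
        return [
            Junction(self.contig, d, a, self.strand) for d, a in self.introns
        ]


def _merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


class AnnotationIndex:
    """Everything downstream metrics need to look up against the annotation.

    Holds the transcripts, per-contig interval trees over merged exon
    unions (for classification), per-gene merged exon intervals (for gene
    assignment without double counting shared exons), gene spans, the
    deduplicated junction set, and the set of ribosomal gene ids (derived
    solely from the biotype attribute).
    """

    def __init__(
        self,
        transcripts: Iterable[TranscriptModel],
        mito_contig: Optional[str] = None,
        extra_contigs: Iterable[str] = (),
    ) -> None:
        self.transcripts: dict[str, TranscriptModel] = {}
        for tx in transcripts:
            if tx.transcript_id in self.transcripts:
                raise ValidationError(f"duplicate transcript id {tx.transcript_id}")
            self.transcripts[tx.transcript_id] = tx

        self.gene_transcripts: dict[str, list[str]] = {}
        for tx in self.transcripts.values():
            self.gene_transcripts.setdefault(tx.gene_id, []).append(tx.transcript_id)
        for tids in self.gene_transcripts.values():
            contigs = {self.transcripts[t].contig for t in tids}
            if len(contigs) > 1:
                raise ValidationError(
                    f"gene {self.transcripts[tids[0]].gene_id} spans contigs {contigs}"
                )

        # gene spans and strand (strand of the first transcript)
        self.gene_span: dict[str, tuple[str, int, int, str]] = {}
        for gid, tids in self.gene_transcripts.items():
            txs = [self.transcripts[t] for t in tids]
            self.gene_span[gid] = (
                txs[0].contig,
                min(t.start for t in txs),
                max(t.end for t in txs),
                txs[0].strand,
            )

        # per-gene merged exon intervals + exonic union length
        self.gene_exons: dict[str, list[tuple[int, int]]] = {}
        for gid, tids in self.gene_transcripts.items():
            ivs = [
                exon for t in tids for exon in self.transcripts[t].exons
            ]
            self.gene_exons[gid] = _merge_intervals(ivs)
        self.gene_exonic_length: dict[str, int] = {
            gid: sum(e - s for s, e in ivs) for gid, ivs in self.gene_exons.items()
        }

        # interval trees
        self.exon_union: dict[str, IntervalTree] = {}
        self.gene_exon_tree: dict[str, IntervalTree] = {}
        self.gene_tree: dict[str, IntervalTree] = {}
        for gid, ivs in self.gene_exons.items():
            contig = self.gene_span[gid][0]
            et = self.exon_union.setdefault(contig, IntervalTree())
            gt = self.gene_exon_tree.setdefault(contig, IntervalTree())
            for s, e in ivs:
                et.addi(s, e)
                gt.addi(s, e, gid)
        for tree in self.exon_union.values():
            tree.merge_overlaps()
        for gid, (contig, s, e, _strand) in self.gene_span.items():
            self.gene_tree.setdefault(contig, IntervalTree()).addi(s, e, gid)

        # junctions, deduplicated by (contig, donor, acceptor, strand)
        self.junctions: set[Junction] = set()
        for tx in self.transcripts.values():
            self.junctions.update(tx.junctions())
        self._junction_lookup: dict[tuple[str, int, int], list[Junction]] = {}
        for j in sorted(self.junctions):
            self._junction_lookup.setdefault(
                (j.contig, j.donor_end, j.acceptor_start), []
            ).append(j)

        self.rrna_genes: set[str] = {
            tx.gene_id
            for tx in self.transcripts.values()
            if "rrna" in tx.biotype.lower()
        }

        self.contigs: set[str] = {t.contig for t in self.transcripts.values()}
        self.contigs.update(extra_contigs)
        if mito_contig is None:
            mito_contig = next(
                (name for name in MITO_NAMES if name in self.contigs), None
            )
        self.mito_contig = mito_contig

    # -- lookups ----------------------------------------------------------

    def register_contigs(self, names: Iterable[str]) -> None:
        """Declare contigs (e.g. from a SAM header) that carry no genes."""
        self.contigs.update(names)

    def _check_contig(self, contig: str) -> None:
        if contig not in self.contigs:
            raise LookupError(f"contig {contig!r} unknown to annotation index")

    def overlap_bases(
        self, blocks: Iterable[tuple[str, int, int]], trees: dict[str, IntervalTree]
    ) -> int:
        total = 0
        for contig, start, end in blocks:
            tree = trees.get(contig)
            if tree is None:
                continue
            for iv in tree.overlap(start, end):
                total += min(end, iv.end) - max(start, iv.begin)
        return total

    def classify(self, blocks: list[tuple[str, int, int]]) -> str:
        """Classify one read's aligned blocks as exonic/intronic/intergenic.

        Majority rule with precedence: exonic when at least half the aligned
        reference bases fall in the exon union, else intronic when at least
        half fall within any gene span, else intergenic.
        """
        for contig, _s, _e in blocks:
            self._check_contig(contig)
        aligned = sum(e - s for _c, s, e in blocks)
        if aligned == 0:
            return "intergenic"
        if self.overlap_bases(blocks, self.exon_union) * 2 >= aligned:
            return "exonic"
        if self.overlap_bases(blocks, self.gene_tree) * 2 >= aligned:
            return "intronic"
        return "intergenic"

    def assign_gene(
        self, blocks: list[tuple[str, int, int]]
    ) -> tuple[Optional[str], bool]:
        """Assign a read's blocks to a single gene by its exon overlaps.

        Returns ``(gene_id, ambiguous)``: a gene id when every
        exon-overlapping base of the read belongs to exactly that gene,
        ``(None, True)`` when two or more genes share the overlap, and
        ``(None, False)`` when no exon is touched.
        """
        per_gene: dict[str, int] = {}
        for contig, start, end in blocks:
            tree = self.gene_exon_tree.get(contig)
            if tree is None:
                continue
            for iv in tree.overlap(start, end):
                ov = min(end, iv.end) - max(start, iv.begin)
                per_gene[iv.data] = per_gene.get(iv.data, 0) + ov
        if not per_gene:
            return None, False
        if len(per_gene) > 1:
            return None, True
        return next(iter(per_gene)), False

    def lookup_junction(
        self, contig: str, donor_end: int, acceptor_start: int
    ) -> list[Junction]:
        return self._junction_lookup.get((contig, donor_end, acceptor_start), [])


def classify_interval_set(
    blocks: list[tuple[str, int, int]], index: AnnotationIndex
) -> str:
    return index.classify(blocks)


def fragment_strand(record: AlignmentRecord, orientation: str) -> Optional[str]:
    """Infer the genomic strand of the originating RNA fragment.

    Under dUTP ("reverse") chemistry the first-in-pair read sequences the
    strand opposite to the transcript, so its mapped strand is flipped;
    the second-in-pair read maps sense.  "forward" chemistry is the mirror
    image.  Returns ``None`` for unstranded libraries.
    """
    if orientation not in ORIENTATIONS:
        raise ValueError(f"unknown orientation {orientation!r}")
    if orientation == "unstranded":
        return None
    read_strand = "-" if record.is_reverse else "+"
    flip = record.is_read1 if orientation == "reverse" else record.is_read2
    if not record.is_paired:
        flip = orientation == "reverse"
    if flip:
        return "+" if read_strand == "-" else "-"
    return read_strand


def junctions_spanned(
    record: AlignmentRecord,
    index: AnnotationIndex,
    min_overhang: int = 3,
    orientation: str = "reverse",
) -> list[tuple[Junction, bool]]:
    """Annotated junctions this read's N-skips span, with sense flags.

    One entry per N operation whose skipped interval equals an annotated
    intron exactly and whose immediately flanking M blocks each cover at
    least ``min_overhang`` reference bases.  ``sense`` is True when the
    inferred fragment strand equals the junction strand.
    """
    if min_overhang < 1:
        raise ValueError("min_overhang must be >= 1")
    if record.is_unmapped or not record.has_skip():
        return []
    strand = fragment_strand(record, orientation)
    out: list[tuple[Junction, bool]] = []
    pos = record.position
    ops = record.cigar
    for i, (op, length) in enumerate(ops):
        if op == "N":
            left_ok = i > 0 and ops[i - 1][0] == "M" and ops[i - 1][1] >= min_overhang
            right_ok = (
                i + 1 < len(ops)
                and ops[i + 1][0] == "M"
                and ops[i + 1][1] >= min_overhang
            )
            if left_ok and right_ok:
                for j in index.lookup_junction(
                    record.reference_name, pos, pos + length
                ):
                    out.append((j, strand == j.strand))
        if op in ("M", "D", "N"):
            pos += length
    return out


# ---------------------------------------------------------------------------
# GTF parsing
# ---------------------------------------------------------------------------

_GTF_COLUMNS = [
    "seqname",
    "source",
    "feature",
    "start",
    "end",
    "score",
    "strand",
    "frame",
    "attribute",
]


def _attr(series: pd.Series, key: str) -> pd.Series:
    return series.str.extract(rf'{key} "([^"]*)"', expand=False)


def parse_gtf(
    path: str | Path,
    mito_contig: Optional[str] = None,
    extra_contigs: Iterable[str] = (),
) -> AnnotationIndex:
    """Build an :class:`AnnotationIndex` from GTF exon rows.

    Transcripts are assembled from their exon rows (gene/transcript rows
    are not required); the junction set is the union over transcripts of
    adjacent-exon pairs, deduplicated across transcripts.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=_GTF_COLUMNS,
        dtype={"start": int, "end": int},
    )
    exons = df[df["feature"] == "exon"].copy()
    if exons.empty:
        raise ParseError(f"{path}: GTF contains no exon rows")
    exons["gene_id"] = _attr(exons["attribute"], "gene_id")
    exons["transcript_id"] = _attr(exons["attribute"], "transcript_id")
    exons["biotype"] = _attr(exons["attribute"], "gene_biotype").fillna(
        "protein_coding"
    )
    if exons["gene_id"].isna().any() or exons["transcript_id"].isna().any():
        bad = exons[exons["gene_id"].isna() | exons["transcript_id"].isna()]
        raise ParseError(
            f"{path}: exon rows missing gene_id/transcript_id "
            f"(first offending seqname={bad.iloc[0]['seqname']})"
        )
    if (exons["end"] < exons["start"]).any():
        raise ValidationError(f"{path}: exon with end < start")

    transcripts = []
    for tid, grp in exons.groupby("transcript_id", sort=True):
        contigs = grp["seqname"].unique()
        if len(contigs) > 1:
            raise ValidationError(
                f"{path}: transcript {tid} spans contigs {list(contigs)}"
            )
        strands = grp["strand"].unique()
        if len(strands) > 1:
            raise ValidationError(f"{path}: transcript {tid} mixes strands")
        ivs = sorted(
            (int(s) - 1, int(e)) for s, e in zip(grp["start"], grp["end"])
        )
        transcripts.append(
            TranscriptModel(
                transcript_id=str(tid),
                gene_id=str(grp["gene_id"].iloc[0]),
                contig=str(contigs[0]),
                strand=str(strands[0]),
                exons=tuple(ivs),
                biotype=str(grp["biotype"].iloc[0]),
            )
        )
    return AnnotationIndex(
        transcripts, mito_contig=mito_contig, extra_contigs=extra_contigs
    )


def write_gtf(transcripts: Iterable[TranscriptModel], path: str | Path) -> None:
    """Write gene/transcript/exon rows (1-based inclusive coordinates)."""
    txs = list(transcripts)
    by_gene: dict[str, list[TranscriptModel]] = {}
    for tx in txs:
        by_gene.setdefault(tx.gene_id, []).append(tx)
    with open(path, "w") as fh:
        for gid in sorted(by_gene):
            group = by_gene[gid]
            contig = group[0].contig
            strand = group[0].strand
            biotype = group[0].biotype
            gs = min(t.start for t in group) + 1
            ge = max(t.end for t in group)
            attrs = f'gene_id "{gid}"; gene_biotype "{biotype}";'
            fh.write(
                f"{contig}\tstrandqc\tgene\t{gs}\t{ge}\t.\t{strand}\t.\t{attrs}\n"
            )
            for tx in sorted(group, key=lambda t: t.transcript_id):
                tattrs = (
                    f'gene_id "{gid}"; transcript_id "{tx.transcript_id}"; '
                    f'gene_biotype "{biotype}";'
                )
                fh.write(
                    f"{contig}\tstrandqc\ttranscript\t{tx.start + 1}\t{tx.end}\t.\t"
                    f"{strand}\t.\t{tattrs}\n"
                )
                for s, e in tx.exons:
                    fh.write(
                        f"{contig}\tstrandqc\texon\t{s + 1}\t{e}\t.\t{strand}\t.\t"
                        f"{tattrs}\n"
                    )
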