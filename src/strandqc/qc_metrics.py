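"""Per-library profiling metrics.

Covers the category percentages (% exonic / intronic / intergenic), % rRNA,
% mitochondrial, gene-level expression and detection, intron/exon ratio,
junction-based strand-specificity, and cross-library expression correlation.

Duplicate-flagged reads are excluded from every metric computed here; the
duplicate rate itself is measured in :mod:`strandqc.insert_dup`.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import AnnotationIndex, junctions_spanned
from .io_model import AlignmentRecord, LibraryMetricsReport


@dataclass
class GeneExpressionVector:
    """Per-gene read counts and RPKM over the full gene universe.

    RPKM = read_count / (exonic_length / 1e3) / (assigned_reads / 1e6),
    where exonic_length is the union of exon bases of the gene and
    assigned_reads the library-wide total of unambiguously assigned reads.
    """

    table: pd.DataFrame  # index: gene_id; columns: read_count, rpkm, exonic_length
    assigned_reads: int

    @classmethod
    def from_counts(
        cls, counts: dict[str, int], index: AnnotationIndex
    ) -> "GeneExpressionVector":
        genes = sorted(index.gene_transcripts)
        read_count = np.array([counts.get(g, 0) for g in genes], dtype=np.int64)
        exonic_length = np.array(
            [index.gene_exonic_length[g] for g in genes], dtype=np.int64
        )
        assigned = int(read_count.sum())
        with np.errstate(divide="ignore", invalid="ignore"):
            rpkm = np.where(
                (read_count > 0) & (assigned > 0),
                read_count / (exonic_length / 1e3) / (assigned / 1e6)
                if assigned
                else 0.0,
                0.0,
            )
        table = pd.DataFrame(
            {"read_count": read_count, "rpkm": rpkm, "exonic_length": exonic_length},
            index=pd.Index(genes, name="gene_id"),
        )
        return cls(table=table, assigned_reads=assigned)

    @property
    def read_counts(self) -> pd.Series:
        return self.table["read_count"]

    @property
    def rpkm(self) -> pd.Series:
        return self.table["rpkm"]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "GeneExpressionVector":
        table = pd.read_csv(path, sep="\t", index_col="gene_id")
        return cls(table=table, assigned_reads=int(table["read_count"].sum()))


@dataclass
class ClassificationTally:
    """Raw counts behind the category percentages and gene assignment."""

    total_records: int = 0
    mapped: int = 0  # mapped records including duplicates
    mapped_nondup: int = 0
    exonic: int = 0
    intronic: int = 0
    intergenic: int = 0
    mitochondrial: int = 0
    rrna_assigned: int = 0
    ambiguous: int = 0

    @property
    def classified(self) -> int:
        return self.exonic + self.intronic + self.intergenic


def _iter_usable(records: Iterable[AlignmentRecord]):
    for rec in records:
        if rec.is_unmapped or rec.is_duplicate:
            continue
        yield rec


def classify_library(
    records: Iterable[AlignmentRecord], index: AnnotationIndex
) -> tuple[ClassificationTally, dict[str, int]]:
    """Single pass over the records: classification and gene assignment.

    A read is assigned to a gene when it is classified exonic and all its
    exon-overlapping bases fall within that single gene; reads whose exon
    overlap is shared between genes are tallied as ambiguous and excluded
    from expression (but still counted in the category percentages).
    """
    tally = ClassificationTally()
    counts: dict[str, int] = {}
    for rec in records:
        tally.total_records += 1
        if rec.is_unmapped:
            continue
        tally.mapped += 1
        if rec.is_duplicate:
            continue
        tally.mapped_nondup += 1
        if rec.reference_name == index.mito_contig:
            tally.mitochondrial += 1
        blocks = [
            (rec.reference_name, s, e) for s, e in rec.reference_blocks()
        ]
        category = index.classify(blocks)
        if category == "exonic":
            tally.exonic += 1
            gene, ambiguous = index.assign_gene(blocks)
            if ambiguous:
                tally.ambiguous += 1
            elif gene is not None:
                counts[gene] = counts.get(gene, 0) + 1
                if gene in index.rrna_genes:
                    tally.rrna_assigned += 1
        elif category == "intronic":
            tally.intronic += 1
        else:
            tally.intergenic += 1
    return tally, counts


def profile_library(
    records: Iterable[AlignmentRecord],
    index: AnnotationIndex,
    min_count: int = 1,
) -> tuple[LibraryMetricsReport, GeneExpressionVector]:
    """Category percentages, expression, detection and intron/exon ratio.

    ``records`` must be duplicate-marked; duplicate reads count toward
    ``total_reads`` and the aligned fraction but are excluded from every
    derived metric.  An empty stream yields a report with ``total_reads``
    0 and null derived fields.
    """
    tally, counts = classify_library(records, index)
    expr = GeneExpressionVector.from_counts(counts, index)
    report = LibraryMetricsReport(total_reads=tally.total_records)
    if tally.total_records == 0:
        return report, expr
    report.aligned_fraction = tally.mapped / tally.total_records
    if tally.classified > 0:
        report.pct_exonic = tally.exonic / tally.classified
        report.pct_intronic = tally.intronic / tally.classified
        report.pct_intergenic = tally.intergenic / tally.classified
    if tally.mapped_nondup > 0:
        report.pct_mitochondrial = tally.mitochondrial / tally.mapped_nondup
        report.pct_rRNA = tally.rrna_assigned / tally.mapped_nondup
    if tally.exonic > 0:
        report.intron_exon_ratio = tally.intronic / tally.exonic
    else:
        warnings.warn("no exonic reads: intron/exon ratio undefined", stacklevel=2)
    report.genes_detected = genes_detected(expr, min_count)
    return report, expr


def strand_specificity(
    records: Iterable[AlignmentRecord],
    index: AnnotationIndex,
    orientation: str = "reverse",
    min_overhang: int = 3,
    literal_denominator: bool = False,
) -> tuple[Optional[float], int]:
    """Fraction of exon-exon junctions with zero antisense spanning reads.

    Per-junction sense/antisense spanning-read counts are accumulated via
    :func:`junctions_spanned`.  By default the denominator is the set of
    junctions observed by at least one spanning read (depth-robust);
    ``literal_denominator=True`` uses all annotated junctions instead.
    Returns ``(value, junctions_observed)``; the value is None when the
    denominator is empty or the library is unstranded.
    """
    if orientation == "unstranded":
        warnings.warn("strand-specificity undefined for unstranded libraries")
        return None, 0
    sense: dict = {}
    anti: dict = {}
    for rec in _iter_usable(records):
        for junction, is_sense in junctions_spanned(
            rec, index, min_overhang=min_overhang, orientation=orientation
        ):
            if is_sense:
                sense[junction] = sense.get(junction, 0) + 1
            else:
                anti[junction] = anti.get(junction, 0) + 1
    observed = set(sense) | set(anti)
    if literal_denominator:
        denominator = len(index.junctions)
        clean = denominator - len(anti)
    else:
        denominator = len(observed)
        clean = sum(1 for j in observed if j not in anti)
    if denominator == 0:
        warnings.warn("no junction-spanning reads: strand-specificity undefined")
        return None, len(observed)
    return clean / denominator, len(observed)


def intron_exon_ratio(
    records: Iterable[AlignmentRecord], index: AnnotationIndex
) -> Optional[float]:
    """Library-wide ratio of intronic to exonic read counts."""
    tally, _counts = classify_library(records, index)
    if tally.exonic == 0:
        warnings.warn("no exonic reads: intron/exon ratio undefined")
        return None
    return tally.intronic / tally.exonic


def genes_detected(expr: GeneExpressionVector, min_count: int = 1) -> int:
    """Number of genes with at least ``min_count`` assigned reads."""
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    return int((expr.read_counts >= min_count).sum())


def expression_correlation(
    a: GeneExpressionVector,
    b: GeneExpressionVector,
    pseudocount: float = 0.1,
) -> Optional[float]:
    """Pearson correlation of log2(RPKM + pseudocount) between two libraries.

    Computed over the union of genes detected (read_count >= 1) in at least
    one of the two libraries; both vectors must share the gene universe.
    """
    if not a.table.index.equals(b.table.index):
        raise ValueError("expression vectors have different gene universes")
    union = (a.read_counts >= 1) | (b.read_counts >= 1)
    if int(union.sum()) < 3:
        warnings.warn("fewer than 3 detected genes: correlation undefined")
        return None
    x = np.log2(a.rpkm[union] + pseudocount)
    y = np.log2(b.rpkm[union] + pseudocount)
    return float(stats.pearsonr(x, y).statistic)
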