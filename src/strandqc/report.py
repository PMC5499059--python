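"""End-to-end per-library QC run and multi-library comparison.

Stage order mirrors a production RNA-seq QC flow: read the alignments,
optionally down-sample to a fixed fragment count so depth-sensitive
metrics are comparable across libraries, mark duplicates, then compute
the profiling, strand-specificity, coverage-bias, error-rate, insert-size
and spike-in blocks and assemble the report.
"""
from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import coverage_bias, error_spikein, insert_dup, qc_metrics
from .annotation import AnnotationIndex, parse_gtf
from .errors import ConsistencyError
from .io_model import (
    AlignmentRecord,
    LibraryMetricsReport,
    ReferenceSet,
    SpikeInPanel,
    read_alignments,
    read_spikein_panel,
)

logger = logging.getLogger("strandqc")


@dataclass
class RunConfig:
    """Input paths and parameters of one QC run."""

    alignments: str
    annotation: str
    reference: Optional[str] = None
    spikein_fasta: Optional[str] = None
    spikein_table: Optional[str] = None
    variant_mask: Optional[str] = None
    orientation: str = "reverse"
    min_overhang: int = 3
    min_count: int = 1
    pseudocount: float = 0.1
    literal_denominator: bool = False
    min_baseq: int = 0
    max_insert: int = 2000
    mito_contig: Optional[str] = None
    min_mean_cov: float = 5.0
    min_length: int = 500
    n_bins: int = 100
    downsample_n: Optional[int] = None
    downsample_seed: int = 0
    downsample_repeats: int = 1
    mark_before_downsample: bool = False

    def validate(self) -> None:
        for name in ("alignments", "annotation"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name} path {p!r} does not exist")
        if self.orientation not in ("reverse", "forward", "unstranded"):
            raise ValueError(f"unknown orientation {self.orientation!r}")
        if self.downsample_repeats < 1:
            raise ValueError("downsample_repeats must be >= 1")


@dataclass
class QCResult:
    report: LibraryMetricsReport
    expression: qc_metrics.GeneExpressionVector
    profile: Optional[coverage_bias.MetaTranscriptProfile] = None
    insert_sizes: Optional[insert_dup.InsertSizeDistribution] = None
    duplicate_summary: Optional[insert_dup.DuplicateSummary] = None
    spikein_result: Optional[error_spikein.SpikeInResult] = None
    repeat_reports: list[LibraryMetricsReport] = field(default_factory=list)


def qc_from_objects(
    records: Sequence[AlignmentRecord],
    index: AnnotationIndex,
    reference: Optional[ReferenceSet] = None,
    panel: Optional[SpikeInPanel] = None,
    config: Optional[RunConfig] = None,
) -> QCResult:
    """Run the full QC stack on in-memory objects.

    ``records`` need not be duplicate-marked; marking (and optional
    down-sampling) happens here according to ``config``.
    """
    cfg = config or RunConfig(alignments="", annotation="")
    records = list(records)
    logger.info("input: %d records", len(records))

    def one_pass(recs, stage_seed):
        if cfg.downsample_n is not None and not cfg.mark_before_downsample:
            recs = insert_dup.downsample(recs, cfg.downsample_n, stage_seed)
            logger.info("downsampled to %d records", len(recs))
        marked, dup_summary = insert_dup.mark_duplicates(recs)
        if cfg.downsample_n is not None and cfg.mark_before_downsample:
            marked = insert_dup.downsample(marked, cfg.downsample_n, stage_seed)
            logger.info("downsampled (post-marking) to %d records", len(marked))
        logger.info(
            "duplicates: %d of %d fragments",
            dup_summary.duplicate_fragments,
            dup_summary.fragments_total,
        )
        report, expr = qc_metrics.profile_library(marked, index, cfg.min_count)
        report.duplicate_rate = dup_summary.duplicate_rate
        ss, n_junc = qc_metrics.strand_specificity(
            marked,
            index,
            orientation=cfg.orientation,
            min_overhang=cfg.min_overhang,
            literal_denominator=cfg.literal_denominator,
        )
        report.strand_specificity = ss
        report.junctions_observed = n_junc

        usable = [r for r in marked if not r.is_unmapped and not r.is_duplicate]
        ratio, profile = coverage_bias.five_prime_three_prime_ratio(
            usable,
            index,
            min_mean_cov=cfg.min_mean_cov,
            min_length=cfg.min_length,
            n_bins=cfg.n_bins,
        )
        report.five_three_ratio = ratio

        if reference is not None:
            mask = (
                error_spikein.read_variant_mask(cfg.variant_mask)
                if cfg.variant_mask
                else None
            )
            tally = error_spikein.base_error_rate(
                usable, reference, mask=mask, min_baseq=cfg.min_baseq
            )
            report.base_error_rate_per_kb = tally.rate_per_kb

        mito = cfg.mito_contig or index.mito_contig
        ins = None
        if mito is not None:
            ins = insert_dup.insert_size_distribution(
                usable, mito, max_insert=cfg.max_insert
            )
            if ins is not None:
                report.insert_size_summary = {
                    "mean": ins.mean,
                    "median": ins.median,
                    "sd": ins.sd,
                }

        spike = None
        if panel is not None:
            pool = error_spikein.extract_spikein_pool(marked)
            spike = error_spikein.align_to_panel(pool, panel)
            report.spikein_correlation = error_spikein.spikein_dose_response(
                spike, panel
            )
            report.spikein_error_rate_per_kb = error_spikein.spikein_error_rate(
                spike, panel
            )
        return report, expr, profile, ins, dup_summary, spike

    if cfg.downsample_n is None or cfg.downsample_repeats == 1:
        report, expr, profile, ins, dup_summary, spike = one_pass(
            records, cfg.downsample_seed
        )
        return QCResult(report, expr, profile, ins, dup_summary, spike)

    # repeated down-sampling: report per-metric means across repeats
    repeats = []
    for i in range(cfg.downsample_repeats):
        repeats.append(one_pass(records, cfg.downsample_seed + i))
    reports = [r[0] for r in repeats]
    mean_report = _mean_report(reports)
    first = repeats[0]
    return QCResult(
        mean_report, first[1], first[2], first[3], first[4], first[5], reports
    )


def _mean_report(reports: list[LibraryMetricsReport]) -> LibraryMetricsReport:
    """Field-wise mean across repeat reports (None if any repeat is None)."""
    out = LibraryMetricsReport()
    for f in dataclasses.fields(LibraryMetricsReport):
        values = [getattr(r, f.name) for r in reports]
        if f.name == "insert_size_summary":
            if all(v is not None for v in values):
                out.insert_size_summary = {
                    k: float(np.mean([v[k] for v in values]))
                    for k in ("mean", "median", "sd")
                }
        elif any(v is None for v in values):
            setattr(out, f.name, None)
        elif f.name in ("total_reads", "junctions_observed", "genes_detected"):
            setattr(out, f.name, int(round(float(np.mean(values)))))
        else:
            setattr(out, f.name, float(np.mean(values)))
    return out


def run_qc(config: RunConfig) -> QCResult:
    """Load the configured inputs and run the full QC stack."""
    config.validate()
    records = list(read_alignments(config.alignments))
    reference = (
        ReferenceSet.from_fasta(config.reference) if config.reference else None
    )
    extra = reference.lengths.keys() if reference else ()
    index = parse_gtf(
        config.annotation, mito_contig=config.mito_contig, extra_contigs=extra
    )
    panel = None
    if config.spikein_fasta and config.spikein_table:
        panel = read_spikein_panel(config.spikein_fasta, config.spikein_table)
    logger.info("run configuration: %s", dataclasses.asdict(config))
    return qc_from_objects(records, index, reference, panel, config)


_SCALAR_COLUMNS = [
    "total_reads",
    "aligned_fraction",
    "pct_exonic",
    "pct_intronic",
    "pct_intergenic",
    "pct_mitochondrial",
    "pct_rRNA",
    "duplicate_rate",
    "strand_specificity",
    "junctions_observed",
    "intron_exon_ratio",
    "genes_detected",
    "five_three_ratio",
    "base_error_rate_per_kb",
    "spikein_error_rate_per_kb",
    "spikein_correlation",
]


def compare_libraries(
    reports: Sequence[LibraryMetricsReport],
    expressions: Sequence[qc_metrics.GeneExpressionVector],
    names: Optional[Sequence[str]] = None,
    pseudocount: float = 0.1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Scalar-metric table plus the pairwise expression correlation matrix.

    All expression vectors must share one gene universe (same annotation);
    the correlation matrix is symmetric with a unit diagonal.
    """
    if len(reports) != len(expressions):
        raise ValueError("reports and expressions differ in length")
    n = len(reports)
    if names is None:
        names = [f"library_{i + 1}" for i in range(n)]
    universe = expressions[0].table.index
    for expr in expressions[1:]:
        if not expr.table.index.equals(universe):
            raise ConsistencyError("expression vectors built on different annotations")

    table = pd.DataFrame(
        [{c: getattr(r, c) for c in _SCALAR_COLUMNS} for r in reports],
        index=pd.Index(names, name="library"),
    )
    matrix = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            r = qc_metrics.expression_correlation(
                expressions[i], expressions[j], pseudocount=pseudocount
            )
            matrix[i, j] = matrix[j, i] = np.nan if r is None else r
    corr = pd.DataFrame(matrix, index=names, columns=names)
    return table, corr
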