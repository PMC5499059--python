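"""Alignment-, reference- and spike-in-level record types and their file I/O.

Every coordinate held inside the package is 0-based, half-open.  SAM input
(1-based) and GTF input (1-based, end-inclusive) are converted exactly once,
at the parsing boundary, and never again downstream.
"""
from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ConsistencyError, ParseError, ValidationError

# SAM flag bits
FLAG_PAIRED = 0x1
FLAG_PROPER_PAIR = 0x2
FLAG_UNMAPPED = 0x4
FLAG_MATE_UNMAPPED = 0x8
FLAG_REVERSE = 0x10
FLAG_MATE_REVERSE = 0x20
FLAG_READ1 = 0x40
FLAG_READ2 = 0x80
FLAG_DUPLICATE = 0x400

#: CIGAR operations the pipeline understands.  Hard clips and padding are
#: rejected on input: the simulator never emits them and silently dropping
#: them would corrupt mismatch and coverage accounting.
SUPPORTED_CIGAR_OPS = frozenset("MIDNS")

_PYSAM_OP_TO_CHAR = {0: "M", 1: "I", 2: "D", 3: "N", 4: "S"}
_CHAR_TO_PYSAM_OP = {v: k for k, v in _PYSAM_OP_TO_CHAR.items()}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(slots=True)
class AlignmentRecord:
    """One read's mapped (or unmapped) observation.

    ``cigar`` is a list of ``(op, length)`` with ``op`` one of M/I/D/N/S.
    Unmapped reads keep their sequence and qualities so the spike-in path
    can consume them without a second input file.
    """

    query_name: str
    flags: int
    reference_name: Optional[str]
    position: Optional[int]
    mapping_quality: int
    cigar: list[tuple[str, int]]
    mate_reference_name: Optional[str]
    mate_position: Optional[int]
    template_length: int
    sequence: str
    base_qualities: list[int]

    # -- flag accessors -------------------------------------------------
    @property
    def is_paired(self) -> bool:
        return bool(self.flags & FLAG_PAIRED)

    @property
    def is_proper_pair(self) -> bool:
        return bool(self.flags & FLAG_PROPER_PAIR)

    @property
    def is_unmapped(self) -> bool:
        return bool(self.flags & FLAG_UNMAPPED)

    @property
    def mate_is_unmapped(self) -> bool:
        return bool(self.flags & FLAG_MATE_UNMAPPED)

    @property
    def is_reverse(self) -> bool:
        return bool(self.flags & FLAG_REVERSE)

    @property
    def is_read1(self) -> bool:
        return bool(self.flags & FLAG_READ1)

    @property
    def is_read2(self) -> bool:
        return bool(self.flags & FLAG_READ2)

    @property
    def is_duplicate(self) -> bool:
        return bool(self.flags & FLAG_DUPLICATE)

    # -- geometry -------------------------------------------------------
    def reference_blocks(self) -> list[tuple[int, int]]:
        """Reference intervals covered by M operations, in order."""
        if self.position is None:
            return []
        blocks: list[tuple[int, int]] = []
        pos = self.position
        for op, length in self.cigar:
            if op == "M":
                blocks.append((pos, pos + length))
                pos += length
            elif op in ("D", "N"):
                pos += length
        return blocks

    @property
    def reference_end(self) -> Optional[int]:
        if self.position is None:
            return None
        return self.position + sum(l for op, l in self.cigar if op in "MDN")

    @property
    def aligned_reference_length(self) -> int:
        return sum(l for op, l in self.cigar if op == "M")

    def has_skip(self) -> bool:
        return any(op == "N" for op, _ in self.cigar)

    def unclipped_five_prime(self) -> int:
        """5' mapping coordinate after backing out soft clips.

        For a forward read this is the leftmost position minus any leading
        soft clip; for a reverse read, the rightmost position plus any
        trailing soft clip (exclusive end convention).
        """
        if self.position is None:
            raise ValueError("unclipped position undefined for unmapped read")
        if self.is_reverse:
            trail = self.cigar[-1][1] if self.cigar and self.cigar[-1][0] == "S" else 0
            return self.reference_end + trail
        lead = self.cigar[0][1] if self.cigar and self.cigar[0][0] == "S" else 0
        return self.position - lead

    # -- validation -----------------------------------------------------
    def validate(self) -> None:
        if self.is_unmapped:
            if self.position is not None or self.cigar:
                raise ValidationError(
                    f"{self.query_name}: unmapped read must have no position/CIGAR"
                )
        elif self.cigar:
            consumed = sum(l for op, l in self.cigar if op in "MIS")
            if consumed != len(self.sequence):
                raise ValidationError(
                    f"{self.query_name}: CIGAR consumes {consumed} query bases "
                    f"but sequence has {len(self.sequence)}"
                )
        if self.is_paired and not (self.is_read1 ^ self.is_read2):
            raise ValidationError(
                f"{self.query_name}: paired read must be first XOR second in pair"
            )
        if self.base_qualities and len(self.base_qualities) != len(self.sequence):
            raise ValidationError(
                f"{self.query_name}: quality string length differs from sequence"
            )
        for op, _ in self.cigar:
            if op not in SUPPORTED_CIGAR_OPS:
                raise ValidationError(f"{self.query_name}: unsupported CIGAR op {op!r}")

    # -- pysam bridge -----------------------------------------------------
    @classmethod
    def from_pysam(cls, a: pysam.AlignedSegment) -> "AlignmentRecord":
        cigar: list[tuple[str, int]] = []
        if a.cigartuples:
            for op, length in a.cigartuples:
                char = _PYSAM_OP_TO_CHAR.get(op)
                if char is None:
                    raise ValidationError(
                        f"{a.query_name}: unsupported CIGAR operation code {op} "
                        "(hard clips and padding are rejected)"
                    )
                cigar.append((char, length))
        quals = list(a.query_qualities) if a.query_qualities is not None else []
        rec = cls(
            query_name=a.query_name,
            flags=a.flag,
            reference_name=a.reference_name if a.reference_id >= 0 else None,
            position=None if a.is_unmapped else a.reference_start,
            mapping_quality=a.mapping_quality,
            cigar=cigar if not a.is_unmapped else [],
            mate_reference_name=(
                a.next_reference_name if a.next_reference_id >= 0 else None
            ),
            mate_position=a.next_reference_start if a.next_reference_id >= 0 else None,
            template_length=a.template_length,
            sequence=a.query_sequence or "",
            base_qualities=quals,
        )
        rec.validate()
        return rec

    def to_pysam(self, header: pysam.AlignmentHeader) -> pysam.AlignedSegment:
        a = pysam.AlignedSegment(header)
        a.query_name = self.query_name
        a.flag = self.flags
        a.reference_id = (
            header.get_tid(self.reference_name) if self.reference_name else -1
        )
        a.reference_start = self.position if self.position is not None else -1
        a.mapping_quality = self.mapping_quality
        if self.cigar:
            a.cigartuples = [(_CHAR_TO_PYSAM_OP[op], l) for op, l in self.cigar]
        a.next_reference_id = (
            header.get_tid(self.mate_reference_name)
            if self.mate_reference_name
            else -1
        )
        a.next_reference_start = (
            self.mate_position if self.mate_position is not None else -1
        )
        a.template_length = self.template_length
        a.query_sequence = self.sequence or None
        if self.base_qualities:
            a.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(q + 33) for q in self.base_qualities)
            )
        return a


def read_alignments(
    path: str | Path, region: Optional[str] = None
) -> Iterator[AlignmentRecord]:
    """Stream records from a SAM file in file order.

    ``region`` restricts output to records whose reference name equals it;
    unmapped records are retained only when no region is given.
    """
    path = str(path)
    with pysam.AlignmentFile(path, "r", check_sq=True) as f:
        if region is not None and region not in f.references:
            raise LookupError(f"contig {region!r} not present in header of {path}")
        n_header = len(str(f.header).rstrip("\n").split("\n"))
        i = 0
        it = f.fetch(until_eof=True)
        while True:
            try:
                a = next(it)
            except StopIteration:
                break
            except (OSError, ValueError) as exc:
                raise ParseError(
                    f"{path}: malformed alignment record at line {n_header + i + 1}: {exc}"
                ) from exc
            i += 1
            try:
                rec = AlignmentRecord.from_pysam(a)
            except ValidationError as exc:
                raise ParseError(
                    f"{path}: invalid record at line {n_header + i}: {exc}"
                ) from exc
            if region is not None:
                if rec.reference_name == region:
                    yield rec
            else:
                yield rec


def write_alignments(
    records: Iterable[AlignmentRecord],
    path: str | Path,
    contig_lengths: Mapping[str, int],
    sort_order: str = "coordinate",
) -> None:
    """Write records to a SAM file with an @SQ line per contig."""
    header = {
        "HD": {"VN": "1.6", "SO": sort_order},
        "SQ": [{"SN": name, "LN": length} for name, length in contig_lengths.items()],
    }
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for rec in records:
            out.write(rec.to_pysam(out.header))


# ---------------------------------------------------------------------------
# Reference genome
# ---------------------------------------------------------------------------


@dataclass
class ReferenceSet:
    """Mapping from contig name to nucleotide sequence."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            bad = set(seq.upper()) - set("ACGTN")
            if bad:
                raise ValidationError(
                    f"contig {name!r} contains non-nucleotide characters {sorted(bad)}"
                )

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    def __contains__(self, contig: str) -> bool:
        return contig in self.sequences

    def fetch(self, contig: str, start: int, end: int) -> str:
        try:
            return self.sequences[contig][start:end]
        except KeyError:
            raise LookupError(f"contig {contig!r} absent from reference") from None

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ReferenceSet":
        seqs = {
            rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
        }
        return cls(seqs)

    def to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(seq), id=name, description="")
            for name, seq in self.sequences.items()
        ]
        SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Spike-in panel
# ---------------------------------------------------------------------------


@dataclass
class SpikeInPanel:
    """Spike-in reference sequences with their expected concentrations.

    Concentrations are in attomoles per microlitre; they define the
    "ground truth" dose axis of the dose-response analysis.
    """

    ids: list[str]
    sequences: dict[str, str]
    concentrations: dict[str, float]

    def __post_init__(self) -> None:
        if len(set(self.ids)) != len(self.ids):
            raise ValidationError("spike-in ids are not unique")
        for sid in self.ids:
            if self.concentrations[sid] <= 0:
                raise ValidationError(
                    f"spike-in {sid}: concentration must be strictly positive"
                )

    def __len__(self) -> int:
        return len(self.ids)

    def length(self, sid: str) -> int:
        return len(self.sequences[sid])

    def to_files(self, fasta_path: str | Path, table_path: str | Path) -> None:
        records = [
            SeqRecord(Seq(self.sequences[sid]), id=sid, description="")
            for sid in self.ids
        ]
        SeqIO.write(records, str(fasta_path), "fasta")
        with open(table_path, "w") as fh:
            fh.write("id\tconcentration\tlength\n")
            for sid in self.ids:
                fh.write(
                    f"{sid}\t{self.concentrations[sid]!r}\t{self.length(sid)}\n"
                )


def read_spikein_panel(
    sequences: str | Path, concentrations: str | Path
) -> SpikeInPanel:
    """Load a spike-in panel from a FASTA file and a tab-delimited table.

    The table must have a header row with ``id``, ``concentration`` and
    ``length`` columns; every id must be present in the FASTA file and the
    tabulated length must match the sequence length.
    """
    import pandas as pd

    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(sequences), "fasta")}
    table = pd.read_csv(concentrations, sep="\t")
    required = {"id", "concentration", "length"}
    if not required.issubset(table.columns):
        raise ParseError(
            f"spike-in table must have columns {sorted(required)}, "
            f"got {list(table.columns)}"
        )
    ids: list[str] = []
    concs: dict[str, float] = {}
    for row in table.itertuples(index=False):
        sid = str(row.id)
        if sid not in seqs:
            raise ConsistencyError(f"spike-in {sid} in table but not in FASTA")
        if float(row.concentration) <= 0:
            raise ValidationError(f"spike-in {sid}: non-positive concentration")
        if int(row.length) != len(seqs[sid]):
            raise ConsistencyError(
                f"spike-in {sid}: table length {row.length} != sequence "
                f"length {len(seqs[sid])}"
            )
        ids.append(sid)
        concs[sid] = float(row.concentration)
    return SpikeInPanel(ids=ids, sequences={i: seqs[i] for i in ids}, concentrations=concs)


# ---------------------------------------------------------------------------
# Per-library metrics report
# ---------------------------------------------------------------------------


@dataclass
class LibraryMetricsReport:
    """The full per-library QC vector.

    Proportions are stored as fractions in [0, 1]; error rates as events per
    kilobase.  Fields that could not be computed (e.g. no mitochondrial
    pairs for the insert-size block) are ``None`` and serialize as JSON
    ``null`` rather than being dropped.
    """

    total_reads: int = 0
    aligned_fraction: Optional[float] = None
    pct_exonic: Optional[float] = None
    pct_intronic: Optional[float] = None
    pct_intergenic: Optional[float] = None
    pct_mitochondrial: Optional[float] = None
    pct_rRNA: Optional[float] = None
    duplicate_rate: Optional[float] = None
    strand_specificity: Optional[float] = None
    junctions_observed: Optional[int] = None
    intron_exon_ratio: Optional[float] = None
    genes_detected: Optional[int] = None
    five_three_ratio: Optional[float] = None
    base_error_rate_per_kb: Optional[float] = None
    spikein_error_rate_per_kb: Optional[float] = None
    spikein_correlation: Optional[float] = None
    insert_size_summary: Optional[dict] = None  # {"mean","median","sd"}

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "LibraryMetricsReport":
        names = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in names})


_METRIC_UNITS = {
    "total_reads": "count",
    "aligned_fraction": "proportion",
    "pct_exonic": "proportion",
    "pct_intronic": "proportion",
    "pct_intergenic": "proportion",
    "pct_mitochondrial": "proportion",
    "pct_rRNA": "proportion",
    "duplicate_rate": "proportion",
    "strand_specificity": "proportion",
    "junctions_observed": "count",
    "intron_exon_ratio": "ratio",
    "genes_detected": "count",
    "five_three_ratio": "ratio",
    "base_error_rate_per_kb": "per_kb",
    "spikein_error_rate_per_kb": "per_kb",
    "spikein_correlation": "pearson_r",
    "insert_size_mean": "nt",
    "insert_size_median": "nt",
    "insert_size_sd": "nt",
}


def _flatten(report: LibraryMetricsReport) -> dict:
    d = report.to_dict()
    ins = d.pop("insert_size_summary")
    for key in ("mean", "median", "sd"):
        d[f"insert_size_{key}"] = None if ins is None else ins[key]
    return d


def write_report(
    report: LibraryMetricsReport, path: str | Path, format: str = "json"
) -> None:
    """Serialize a report; a JSON round trip is numerically exact."""
    if format == "json":
        with open(path, "w") as fh:
            json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
    elif format == "tsv":
        with open(path, "w") as fh:
            fh.write("metric\tvalue\tunits\n")
            for name, value in _flatten(report).items():
                text = "NA" if value is None else repr(value)
                fh.write(f"{name}\t{text}\t{_METRIC_UNITS[name]}\n")
    else:
        raise ValueError(f"unknown report format {format!r}")


def read_report(path: str | Path, format: str = "json") -> LibraryMetricsReport:
    if format == "json":
        with open(path) as fh:
            return LibraryMetricsReport.from_dict(json.load(fh))
    if format == "tsv":
        values: dict = {}
        with open(path) as fh:
            header = fh.readline()
            for line in fh:
                name, text, _units = line.rstrip("\n").split("\t")
                if text == "NA":
                    values[name] = None
                elif name in ("total_reads", "junctions_observed", "genes_detected"):
                    values[name] = int(text)
                else:
                    values[name] = float(text)
        ins_keys = ("insert_size_mean", "insert_size_median", "insert_size_sd")
        ins = {k.removeprefix("insert_size_"): values.pop(k) for k in ins_keys}
        summary = None if all(v is None for v in ins.values()) else ins
        return LibraryMetricsReport(**values, insert_size_summary=summary)
    raise ValueError(f"unknown report format {format!r}")
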