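"""Base error rates by mismatch counting, and the spike-in analysis.

The spike-in path mirrors how a sequencing facility benchmarks library
chemistry with a synthetic RNA panel of known concentrations: read pairs
with at least one unmapped mate are pooled, re-matched against the panel
with a gapless seed-and-extend aligner requiring a highly specific match,
and the assigned counts drive a log-log dose-response correlation and a
panel-based per-kilobase error rate.

Known-variant positions can be excluded from genomic mismatch counting via
an optional mask rather than a variant caller: the statistic is used for
relative comparisons between libraries, where the SNP contribution is a
shared, tolerable offset.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
from scipy import stats

from .io_model import AlignmentRecord, ReferenceSet, SpikeInPanel, reverse_complement


@dataclass
class MismatchTally:
    aligned_bases: int = 0
    mismatches: int = 0
    masked_bases: int = 0
    per_contig: dict = field(default_factory=dict)  # contig -> [bases, mismatches]

    @property
    def rate(self) -> float:
        """Mismatches per aligned base."""
        return self.mismatches / self.aligned_bases if self.aligned_bases else 0.0

    @property
    def rate_per_kb(self) -> float:
        return self.rate * 1000.0


def read_variant_mask(path: str | Path) -> set[tuple[str, int]]:
    """Load masked positions from a BED file (0-based half-open intervals)."""
    masked: set[tuple[str, int]] = set()
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            contig, start, end = line.split("\t")[:3]
            for pos in range(int(start), int(end)):
                masked.add((contig, pos))
    return masked


def base_error_rate(
    records: Iterable[AlignmentRecord],
    reference: ReferenceSet,
    mask: Optional[set[tuple[str, int]]] = None,
    min_baseq: int = 0,
) -> MismatchTally:
    """Count substitutions in M-operation bases against the reference.

    Soft-clipped, inserted, deleted and N-skipped bases are excluded from
    both numerator and denominator, as are bases below ``min_baseq``,
    masked positions, and reference N bases.
    """
    tally = MismatchTally()
    masked_by_contig: dict[str, np.ndarray] = {}
    if mask:
        tmp: dict[str, list[int]] = {}
        for contig, pos in mask:
            tmp.setdefault(contig, []).append(pos)
        masked_by_contig = {c: np.array(sorted(p)) for c, p in tmp.items()}

    for rec in records:
        if rec.is_unmapped:
            continue
        contig = rec.reference_name
        if contig not in reference:
            raise LookupError(f"contig {contig!r} absent from reference")
        refseq = reference.sequences[contig]
        qpos = 0
        rpos = rec.position
        for op, length in rec.cigar:
            if op == "M":
                q = np.frombuffer(
                    rec.sequence[qpos : qpos + length].upper().encode(), dtype=np.uint8
                )
                r = np.frombuffer(
                    refseq[rpos : rpos + length].upper().encode(), dtype=np.uint8
                )
                valid = r != ord("N")
                if min_baseq > 0 and rec.base_qualities:
                    quals = np.asarray(rec.base_qualities[qpos : qpos + length])
                    valid &= quals >= min_baseq
                cmask = masked_by_contig.get(contig)
                if cmask is not None:
                    positions = rpos + np.arange(length)
                    hit = np.isin(positions, cmask)
                    tally.masked_bases += int((hit & valid).sum())
                    valid &= ~hit
                n_bases = int(valid.sum())
                n_mm = int(((q != r) & valid).sum())
                tally.aligned_bases += n_bases
                tally.mismatches += n_mm
                entry = tally.per_contig.setdefault(contig, [0, 0])
                entry[0] += n_bases
                entry[1] += n_mm
                qpos += length
                rpos += length
            elif op in ("I", "S"):
                qpos += length
            elif op in ("D", "N"):
                rpos += length
    return tally


# ---------------------------------------------------------------------------
# Spike-in pool and realignment
# ---------------------------------------------------------------------------


def extract_spikein_pool(
    records: Iterable[AlignmentRecord],
) -> list[list[AlignmentRecord]]:
    """Read pairs where at least one mate carries the unmapped flag.

    Both mates of a selected pair are returned.  A selected read whose
    mate is missing from the stream is kept as a singleton with a warning.
    """
    pairs: dict[str, list[AlignmentRecord]] = {}
    for rec in records:
        if not rec.is_paired:
            continue
        pairs.setdefault(rec.query_name, []).append(rec)
    pool: list[list[AlignmentRecord]] = []
    for name in pairs:
        mates = pairs[name]
        if any(m.is_unmapped for m in mates):
            if len(mates) == 1 and not (
                mates[0].is_unmapped and mates[0].mate_is_unmapped
            ):
                warnings.warn(f"mate of {name} missing from stream; keeping singleton")
            pool.append(mates)
    return pool


@dataclass
class SpikeInAssignment:
    query_name: str
    spikein_id: str
    orientation: str  # "+" read matches panel forward, "-" reverse complement
    span: int
    mismatches: int

    @property
    def identity(self) -> float:
        return (self.span - self.mismatches) / self.span


@dataclass
class SpikeInResult:
    assigned_counts: dict[str, int]
    assignments: list[SpikeInAssignment]
    pool_size: int  # reads examined
    unassigned_reads: int

    def abundances(self, panel: SpikeInPanel) -> dict[str, float]:
        """Reads per kilobase of spike-in sequence, per panel member."""
        return {
            sid: n / (panel.length(sid) / 1000.0)
            for sid, n in self.assigned_counts.items()
        }


def _hamming(a: str, b: str) -> int:
    x = np.frombuffer(a.encode(), dtype=np.uint8)
    y = np.frombuffer(b.encode(), dtype=np.uint8)
    return int((x != y).sum())


def align_to_panel(
    pool: Sequence[Sequence[AlignmentRecord]],
    panel: SpikeInPanel,
    seed_length: int = 20,
    min_identity: float = 0.95,
    min_cov: float = 0.9,
) -> SpikeInResult:
    """Gapless seed-and-extend matching of pooled reads against the panel.

    For each read, every exact ``seed_length``-mer shared with a panel
    sequence (either orientation) anchors a gapless extension over the
    full read; the read is assigned to the spike-in with the highest
    identity provided identity >= ``min_identity`` and the aligned span
    covers >= ``min_cov`` of the read.  Ties break by longest span, then
    lexicographically smallest id.  Deterministic regardless of read order.
    """
    if len(panel) == 0:
        raise ValueError("spike-in panel is empty")
    k = seed_length
    seeds: dict[str, list[tuple[str, str, int]]] = {}
    targets: dict[tuple[str, str], str] = {}
    for sid in sorted(panel.ids):
        fwd = panel.sequences[sid]
        for orient, seq in (("+", fwd), ("-", reverse_complement(fwd))):
            targets[(sid, orient)] = seq
            for i in range(len(seq) - k + 1):
                seeds.setdefault(seq[i : i + k], []).append((sid, orient, i))

    counts: dict[str, int] = {}
    assignments: list[SpikeInAssignment] = []
    pool_size = 0
    unassigned = 0
    for mates in pool:
        for rec in mates:
            seq = rec.sequence.upper()
            if len(seq) < k:
                continue
            pool_size += 1
            candidates: set[tuple[str, str, int]] = set()
            for qpos in range(len(seq) - k + 1):
                for sid, orient, tpos in seeds.get(seq[qpos : qpos + k], ()):
                    candidates.add((sid, orient, tpos - qpos))
            best: Optional[SpikeInAssignment] = None
            for sid, orient, offset in sorted(candidates):
                target = targets[(sid, orient)]
                qstart = max(0, -offset)
                qend = min(len(seq), len(target) - offset)
                span = qend - qstart
                if span <= 0:
                    continue
                mm = _hamming(
                    seq[qstart:qend], target[qstart + offset : qend + offset]
                )
                cand = SpikeInAssignment(rec.query_name, sid, orient, span, mm)
                if cand.identity < min_identity or span < min_cov * len(seq):
                    continue
                if (
                    best is None
                    or cand.identity > best.identity
                    or (cand.identity == best.identity and cand.span > best.span)
                    or (
                        cand.identity == best.identity
                        and cand.span == best.span
                        and cand.spikein_id < best.spikein_id
                    )
                ):
                    best = cand
            if best is None:
                unassigned += 1
            else:
                assignments.append(best)
                counts[best.spikein_id] = counts.get(best.spikein_id, 0) + 1
    return SpikeInResult(
        assigned_counts=counts,
        assignments=assignments,
        pool_size=pool_size,
        unassigned_reads=unassigned,
    )


def spikein_dose_response(
    counts: Union[SpikeInResult, Mapping[str, float]],
    panel: SpikeInPanel,
    pseudocount: Union[float, str] = 0.0,
) -> Optional[float]:
    """Pearson r of log2 observed abundance vs log2 expected concentration.

    Observed abundance is assigned reads per kilobase of spike-in
    sequence; only detected members (>= 1 read) enter, so the default
    pseudocount of 0 is well defined and keeps a perfectly proportional
    input at r == 1.  ``pseudocount="half_min"`` uses half the smallest
    nonzero abundance instead.
    """
    if isinstance(counts, SpikeInResult):
        counts = counts.assigned_counts
    detected = sorted(sid for sid, n in counts.items() if n >= 1)
    if len(detected) < 3:
        warnings.warn("fewer than 3 detected spike-ins: dose-response undefined")
        return None
    ab = np.array([counts[sid] / (panel.length(sid) / 1000.0) for sid in detected])
    conc = np.array([panel.concentrations[sid] for sid in detected])
    if pseudocount == "half_min":
        pseudocount = float(ab[ab > 0].min()) / 2.0
    r = stats.pearsonr(np.log2(ab + pseudocount), np.log2(conc)).statistic
    return float(r)


def spikein_error_rate(
    result: SpikeInResult, panel: SpikeInPanel
) -> Optional[float]:
    """Mismatches per 1000 nt over the aligned spans of assigned reads."""
    bases = sum(a.span for a in result.assignments)
    if bases == 0:
        warnings.warn("no assigned spike-in bases: error rate undefined")
        return None
    mismatches = sum(a.mismatches for a in result.assignments)
    return mismatches / bases * 1000.0
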