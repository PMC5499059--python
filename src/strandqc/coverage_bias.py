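"""Meta-transcript coverage profile and the 5'-to-3' coverage-bias ratio.

Each eligible transcript's exonic per-base coverage is oriented 5'->3',
normalized by its own mean, rebinned to a fixed number of bins, and the
bin vectors are averaged across transcripts.  The 5'/3' ratio is the mean
of the first window of bins over the mean of the last window; a value
near 1 indicates an unbiased library, below 1 a 3'-biased one.
"""
from __future__ import annotations

import bisect
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .annotation import AnnotationIndex, TranscriptModel
from .io_model import AlignmentRecord


@dataclass
class MetaTranscriptProfile:
    n_bins: int
    mean_normalized_coverage: np.ndarray  # ordered 5' -> 3'
    transcripts_used: int

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("bin\tmean_normalized_coverage\n")
            for i, v in enumerate(self.mean_normalized_coverage):
                fh.write(f"{i}\t{v!r}\n")


def transcript_coverage(
    records: Iterable[AlignmentRecord],
    transcript: TranscriptModel,
    contigs: Optional[Sequence[str]] = None,
) -> np.ndarray:
    """Per-base read coverage in transcript coordinates (index 0 = 5' end).

    Coverage is counted over exonic bases only: each M block of a record
    contributes +1 to every transcript base it overlaps.  For minus-strand
    transcripts the vector is reversed so that index 0 is the genomic
    right end.
    """
    if contigs is not None and transcript.contig not in contigs:
        raise LookupError(f"transcript contig {transcript.contig!r} unknown")
    cov = np.zeros(transcript.length, dtype=np.float64)
    # transcript offset of each exon, in genomic order
    offsets = np.cumsum([0] + [e - s for s, e in transcript.exons[:-1]])
    exons = transcript.exons
    for rec in records:
        if rec.is_unmapped or rec.reference_name != transcript.contig:
            continue
        for bs, be in rec.reference_blocks():
            if be <= exons[0][0] or bs >= exons[-1][1]:
                continue
            for (es, ee), off in zip(exons, offsets):
                s = max(bs, es)
                e = min(be, ee)
                if e > s:
                    cov[off + (s - es) : off + (e - es)] += 1.0
    if transcript.strand == "-":
        cov = cov[::-1]
    return cov


def bin_coverage(cov: np.ndarray, n_bins: int) -> np.ndarray:
    """Rebin a per-base vector to ``n_bins`` by within-bin means."""
    length = len(cov)
    if length < n_bins:
        raise ValueError(f"vector of length {length} cannot fill {n_bins} bins")
    idx = (np.arange(length) * n_bins) // length
    sums = np.bincount(idx, weights=cov, minlength=n_bins)
    sizes = np.bincount(idx, minlength=n_bins)
    return sums / sizes


def ratio_from_profile(profile: np.ndarray, window_frac: float = 0.2) -> Optional[float]:
    """Mean of the 5' window over the mean of the 3' window."""
    n = len(profile)
    w = max(1, int(round(n * window_frac)))
    head = float(np.mean(profile[:w]))
    tail = float(np.mean(profile[n - w :]))
    if tail == 0:
        warnings.warn("zero coverage in 3' window: ratio undefined")
        return None
    return head / tail


def five_prime_three_prime_ratio(
    records: Iterable[AlignmentRecord],
    index: AnnotationIndex,
    min_mean_cov: float = 5.0,
    min_length: int = 500,
    n_bins: int = 100,
    window_frac: float = 0.2,
) -> tuple[Optional[float], MetaTranscriptProfile]:
    """5'/3' coverage-bias ratio over the meta-transcript profile.

    Eligible transcripts have spliced length >= ``min_length`` and mean
    exonic coverage >= ``min_mean_cov``; each gene contributes only its
    longest transcript so shared exons are not double counted.  Each
    eligible transcript's binned coverage is normalized by its own mean
    before averaging, so highly expressed transcripts do not dominate.
    Returns ``(ratio or None, profile)``.
    """
    if min_mean_cov <= 0:
        raise ValueError("min_mean_cov must be > 0")
    if min_length < n_bins:
        raise ValueError("min_length must be >= n_bins")

    # longest transcript per gene
    chosen: list[TranscriptModel] = []
    for gid, tids in index.gene_transcripts.items():
        txs = [index.transcripts[t] for t in tids]
        chosen.append(max(txs, key=lambda t: (t.length, t.transcript_id)))

    # bucket usable records per contig, sorted by start, for windowed lookup
    by_contig: dict[str, list[AlignmentRecord]] = {}
    for rec in records:
        if rec.is_unmapped or rec.is_duplicate:
            continue
        by_contig.setdefault(rec.reference_name, []).append(rec)
    starts: dict[str, list[int]] = {}
    max_span: dict[str, int] = {}
    for contig, recs in by_contig.items():
        recs.sort(key=lambda r: r.position)
        starts[contig] = [r.position for r in recs]
        max_span[contig] = max(r.reference_end - r.position for r in recs)

    vectors = []
    for tx in sorted(chosen, key=lambda t: t.transcript_id):
        if tx.length < min_length:
            continue
        recs = by_contig.get(tx.contig)
        if not recs:
            continue
        lo = bisect.bisect_left(starts[tx.contig], tx.start - max_span[tx.contig])
        hi = bisect.bisect_right(starts[tx.contig], tx.end)
        cov = transcript_coverage(recs[lo:hi], tx)
        mean = cov.mean()
        if mean < min_mean_cov:
            continue
        binned = bin_coverage(cov, n_bins)
        vectors.append(binned / binned.mean())

    if not vectors:
        profile = MetaTranscriptProfile(n_bins, np.zeros(n_bins), 0)
        warnings.warn("no transcript passed coverage-bias eligibility")
        return None, profile
    mean_profile = np.mean(vectors, axis=0)
    profile = MetaTranscriptProfile(n_bins, mean_profile, len(vectors))
    return ratio_from_profile(mean_profile, window_frac), profile
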