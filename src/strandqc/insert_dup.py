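"""Insert sizes, seeded pair-preserving down-sampling, duplicate marking.

Insert sizes are estimated from pairs on the mitochondrial contig: its
transcripts are unspliced and deeply covered, so the outer template length
is the fragment length without splicing artifacts.  Down-sampling selects
an exact number of fragments (query names) rather than per-read Bernoulli
thinning, so depth-matched comparisons carry no extra sampling noise.
"""
from __future__ import annotations

import dataclasses
import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .io_model import FLAG_DUPLICATE, AlignmentRecord


@dataclass
class InsertSizeDistribution:
    histogram: dict[int, int]
    mean: float
    median: float
    sd: float
    pairs_used: int
    source_contig: str

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("insert_size\tpairs\n")
            for size in sorted(self.histogram):
                fh.write(f"{size}\t{self.histogram[size]}\n")


@dataclass
class DuplicateSummary:
    fragments_total: int
    duplicate_fragments: int
    duplicate_rate: float
    downsample_n: Optional[int] = None
    seed: Optional[int] = None


def insert_size_distribution(
    records: Iterable[AlignmentRecord],
    contig: str,
    max_insert: int = 2000,
) -> Optional[InsertSizeDistribution]:
    """Insert-size histogram from proper pairs on one contig.

    Uses pairs where both mates map to ``contig``, the proper-pair flag is
    set and neither CIGAR contains an N skip; the insert is the positive
    template length of the leftmost mate, taken once per pair.  Pairs with
    insert 0 or above ``max_insert`` are excluded.  Returns None (with a
    warning) when no pair qualifies.
    """
    if max_insert <= 0:
        raise ValueError("max_insert must be > 0")
    pairs: dict[str, list[AlignmentRecord]] = {}
    for rec in records:
        if (
            rec.is_unmapped
            or not rec.is_proper_pair
            or rec.reference_name != contig
            or rec.mate_reference_name != contig
        ):
            continue
        pairs.setdefault(rec.query_name, []).append(rec)

    hist: Counter = Counter()
    for name, mates in pairs.items():
        if len(mates) != 2 or any(m.has_skip() for m in mates):
            continue
        tlen = max(m.template_length for m in mates)
        if 0 < tlen <= max_insert:
            hist[tlen] += 1
    if not hist:
        warnings.warn(f"no qualifying pairs on {contig!r}: insert size undefined")
        return None
    sizes = np.repeat(
        np.fromiter(hist.keys(), dtype=np.int64),
        np.fromiter(hist.values(), dtype=np.int64),
    )
    return InsertSizeDistribution(
        histogram=dict(sorted(hist.items())),
        mean=float(sizes.mean()),
        median=float(np.median(sizes)),
        sd=float(sizes.std(ddof=1)) if len(sizes) > 1 else 0.0,
        pairs_used=int(sizes.size),
        source_contig=contig,
    )


def downsample(
    records: Sequence[AlignmentRecord], n_fragments: int, seed: int
) -> list[AlignmentRecord]:
    """Keep exactly ``n_fragments`` distinct query names, chosen uniformly.

    All records sharing a selected name are kept together, in input order;
    the same seed and input always give the same selection.
    """
    names = sorted({rec.query_name for rec in records})
    if n_fragments > len(names):
        raise ValueError(
            f"requested {n_fragments} fragments but only {len(names)} present"
        )
    rng = np.random.default_rng(seed)
    chosen = set(rng.choice(names, size=n_fragments, replace=False))
    return [rec for rec in records if rec.query_name in chosen]


def _fragment_key(mates: list[AlignmentRecord]):
    mapped = [m for m in mates if not m.is_unmapped]
    if not mapped:
        return None
    if len(mapped) == 2:
        r1 = next((m for m in mapped if m.is_read1), mapped[0])
        r2 = next((m for m in mapped if m is not r1), mapped[-1])
        return (
            r1.reference_name,
            r1.unclipped_five_prime(),
            r1.is_reverse,
            r2.reference_name,
            r2.unclipped_five_prime(),
            r2.is_reverse,
        )
    m = mapped[0]
    return (m.reference_name, m.unclipped_five_prime(), m.is_reverse, None, None, None)


def mark_duplicates(
    records: Sequence[AlignmentRecord],
) -> tuple[list[AlignmentRecord], DuplicateSummary]:
    """Flag PCR duplicates by identical unclipped fragment endpoints.

    The fragment key is (contig, unclipped 5' position, strand) of each
    mapped mate, read1 first.  Within a key group the fragment with the
    highest summed base quality is kept (ties go to the lexicographically
    first query name); all records of the other fragments are flagged on
    both mates.  Fragments with no mapped mate are never flagged and do
    not enter the rate.  Unpaired records fall back to a single-end key
    with a warning.
    """
    by_name: dict[str, list[AlignmentRecord]] = {}
    for rec in records:
        by_name.setdefault(rec.query_name, []).append(rec)

    warned_single = False
    groups: dict[tuple, list[tuple[int, str]]] = {}  # key -> [(score, name)]
    for name, mates in by_name.items():
        if any(not m.is_paired for m in mates) and not warned_single:
            warnings.warn("unpaired records present; using single-end keys")
            warned_single = True
        key = _fragment_key(mates)
        if key is None:
            continue
        score = sum(sum(m.base_qualities) for m in mates)
        groups.setdefault(key, []).append((score, name))

    duplicates: set[str] = set()
    fragments_total = 0
    for key, members in groups.items():
        fragments_total += len(members)
        if len(members) > 1:
            best = min(members, key=lambda t: (-t[0], t[1]))
            for _score, name in members:
                if name != best[1]:
                    duplicates.add(name)

    out: list[AlignmentRecord] = []
    for rec in records:
        if rec.query_name in duplicates:
            if not rec.is_duplicate:
                rec = dataclasses.replace(rec, flags=rec.flags | FLAG_DUPLICATE)
        elif rec.is_duplicate:
            rec = dataclasses.replace(rec, flags=rec.flags & ~FLAG_DUPLICATE)
        out.append(rec)

    rate = len(duplicates) / fragments_total if fragments_total else 0.0
    summary = DuplicateSummary(
        fragments_total=fragments_total,
        duplicate_fragments=len(duplicates),
        duplicate_rate=rate,
    )
    return out, summary
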