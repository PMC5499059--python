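"""Synthetic references, annotation, spike-in panels and aligned read pairs.

The generator emulates a strand-specific (dUTP-chemistry) paired-end
RNA-seq library on a toy genome: a multi-gene spliced transcriptome on two
autosome-like contigs, an unspliced mitochondrial contig, ribosomal genes,
configurable antisense contamination, substitution errors, PCR duplication,
fragment-length distribution, 3' positional bias, and an external spike-in
panel of 92 synthetic RNAs at known concentrations emitted as unmapped
pairs.  Every fragment's generative parameters are recorded in a
:class:`SimulationTruth` so each downstream metric can be validated by
parameter recovery.

Reads are emitted as already-aligned records with correct spliced CIGARs
rather than FASTQ, because every pipeline stage under study starts
downstream of alignment.
"""
from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .annotation import TranscriptModel, write_gtf
from .errors import ValidationError
from .io_model import (
    FLAG_MATE_REVERSE,
    FLAG_MATE_UNMAPPED,
    FLAG_PAIRED,
    FLAG_PROPER_PAIR,
    FLAG_READ1,
    FLAG_READ2,
    FLAG_REVERSE,
    FLAG_UNMAPPED,
    AlignmentRecord,
    ReferenceSet,
    SpikeInPanel,
    write_alignments,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulationConfig:
    """All generative knobs of one simulated library.

    Category fractions (rRNA, mitochondrial, intronic, intergenic,
    spike-in) must sum to at most 1; the remainder is spliced exonic
    signal.  ``three_prime_bias`` of 0 draws fragment starts uniformly
    along the transcript; larger values weight starts exponentially toward
    the 3' end.  ``duplication_mean_extra`` is the mean number of extra
    PCR copies per fragment (geometric).
    """

    seed: int = 0
    # gene geometry
    n_genes: int = 300
    exons_per_gene: tuple[int, int] = (2, 6)
    exon_length: tuple[int, int] = (150, 400)
    intron_length: tuple[int, int] = (200, 800)
    gene_spacing: tuple[int, int] = (500, 3000)
    n_rrna_genes: int = 2
    rrna_gene_length: tuple[int, int] = (1500, 5000)
    n_mito_genes: int = 3
    mito_gene_length: tuple[int, int] = (1000, 2500)
    # library
    expression_dispersion: float = 1.0  # lognormal sigma on gene weights
    #: seed for the expression weights alone; defaults to ``seed``.  Give two
    #: libraries the same value (and different ``seed``) to simulate
    #: technical replicates drawn from one expression truth.
    expression_seed: Optional[int] = None
    n_fragments: int = 20000
    fragment_mean: float = 300.0
    fragment_sd: float = 30.0
    read_length: int = 75
    antisense_rate: float = 0.0
    substitution_rate: float = 0.0
    duplication_mean_extra: float = 0.0
    three_prime_bias: float = 0.0
    rrna_fraction: float = 0.02
    mito_fraction: float = 0.05
    intronic_fraction: float = 0.15
    intergenic_fraction: float = 0.03
    spikein_fraction: float = 0.03
    orientation: str = "reverse"
    # spike-in panel
    n_spikeins: int = 92
    spikein_length: tuple[int, int] = (250, 2000)
    spikein_conc_range: tuple[float, float] = (1e-2, 1e2)
    spikein_half_mapped: float = 0.1  # fraction of pairs with one mapped mate

    def validate(self) -> None:
        fractions = (
            self.rrna_fraction
            + self.mito_fraction
            + self.intronic_fraction
            + self.intergenic_fraction
            + self.spikein_fraction
        )
        if fractions > 1.0 + 1e-12:
            raise ValidationError("category fractions sum above 1")
        for name in ("antisense_rate", "substitution_rate", "spikein_half_mapped"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.orientation not in ("reverse", "forward", "unstranded"):
            raise ValidationError(f"unknown orientation {self.orientation!r}")
        if self.read_length < 1 or self.n_fragments < 0:
            raise ValidationError("read_length/n_fragments out of range")

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d = {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        fields = {f.name: f for f in dataclasses.fields(cls)}
        kwargs = {}
        for k, v in d.items():
            if k not in fields:
                raise ValidationError(f"unknown simulation parameter {k!r}")
            kwargs[k] = tuple(v) if isinstance(v, list) else v
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg


@dataclass
class SimulationTruth:
    """Ground truth for one simulated library.

    ``fragments`` has one row per unique fragment: category, source id,
    RNA strand, sense flag, coordinates, PCR copy count, substitution
    count, and whether the fragment has a mapped read.
    """

    config: SimulationConfig
    expression_weights: dict[str, float]
    fragments: pd.DataFrame

    @property
    def duplicate_fraction_mapped(self) -> float:
        """Ground-truth duplicate fraction over fragments with mapped reads."""
        f = self.fragments[self.fragments["has_mapped"]]
        total = int(f["n_copies"].sum())
        return 1.0 - len(f) / total if total else 0.0

    def category_read_fractions(self) -> dict[str, float]:
        """Fraction of emitted mapped reads per truth category."""
        f = self.fragments[self.fragments["has_mapped"]]
        weights = f["n_copies"] * f["mapped_reads_per_copy"]
        total = float(weights.sum())
        out: dict[str, float] = {}
        for cat, grp in f.groupby("category"):
            out[str(cat)] = float((grp["n_copies"] * grp["mapped_reads_per_copy"]).sum()) / total
        return out

    def to_tsv(self, path) -> None:
        self.fragments.to_csv(path, sep="\t", index=False)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, length)].tobytes().decode()


def generate_reference_and_annotation(
    config: SimulationConfig,
) -> tuple[ReferenceSet, list[TranscriptModel], SpikeInPanel]:
    """Toy genome, one-transcript-per-gene annotation, and spike-in panel.

    Genes alternate between two autosome-like contigs with random spacing;
    ribosomal genes (biotype rRNA) are single-exon on chr1, mitochondrial
    genes single-exon on chrM.  Spike-in concentrations are log-uniform
    over the configured range (four orders of magnitude by default).
    Fully reproducible from the seed.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    transcripts: list[TranscriptModel] = []
    cursors = {"chr1": 1000, "chr2": 1000}

    def place_gene(contig: str, gid: str, exon_lens, intron_lens, strand, biotype):
        start = cursors[contig]
        exons = []
        pos = start
        for i, el in enumerate(exon_lens):
            exons.append((pos, pos + int(el)))
            pos += int(el)
            if i < len(intron_lens):
                pos += int(intron_lens[i])
        cursors[contig] = pos + int(rng.integers(*config.gene_spacing))
        transcripts.append(
            TranscriptModel(
                transcript_id=f"{gid}.1",
                gene_id=gid,
                contig=contig,
                strand=strand,
                exons=tuple(exons),
                biotype=biotype,
            )
        )

    for i in range(config.n_genes):
        contig = "chr1" if i % 2 == 0 else "chr2"
        n_exons = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        exon_lens = rng.integers(config.exon_length[0], config.exon_length[1] + 1, n_exons)
        intron_lens = rng.integers(
            config.intron_length[0], config.intron_length[1] + 1, max(0, n_exons - 1)
        )
        strand = "+" if rng.random() < 0.5 else "-"
        place_gene(contig, f"GENE{i:05d}", exon_lens, intron_lens, strand, "protein_coding")

    for i in range(config.n_rrna_genes):
        length = int(rng.integers(*config.rrna_gene_length))
        strand = "+" if rng.random() < 0.5 else "-"
        place_gene("chr1", f"RRNA{i:03d}", [length], [], strand, "rRNA")

    cursors["chrM"] = 500
    for i in range(config.n_mito_genes):
        length = int(rng.integers(*config.mito_gene_length))
        strand = "+" if rng.random() < 0.5 else "-"
        place_gene("chrM", f"MITO{i:03d}", [length], [], strand, "protein_coding")

    lengths = {
        contig: cursors[contig] + 2000 for contig in ("chr1", "chr2", "chrM")
    }
    reference = ReferenceSet(
        {contig: _random_seq(rng, n) for contig, n in lengths.items()}
    )

    ids = [f"ERCC-{i + 1:05d}" for i in range(config.n_spikeins)]
    lo, hi = config.spikein_conc_range
    concs = 10 ** rng.uniform(math.log10(lo), math.log10(hi), config.n_spikeins)
    slens = rng.integers(
        config.spikein_length[0], config.spikein_length[1] + 1, config.n_spikeins
    )
    panel = SpikeInPanel(
        ids=ids,
        sequences={sid: _random_seq(rng, int(n)) for sid, n in zip(ids, slens)},
        concentrations={sid: float(c) for sid, c in zip(ids, concs)},
    )
    return reference, transcripts, panel


# ---------------------------------------------------------------------------
# library simulation
# ---------------------------------------------------------------------------


def _tx_interval_to_blocks(
    tx: TranscriptModel, start: int, end: int
) -> list[tuple[int, int]]:
    """Map a transcript-coordinate interval (5'->3') to genomic blocks."""
    # cumulative spliced offsets in genomic exon order
    blocks: list[tuple[int, int]] = []
    if tx.strand == "-":
        # transcript coord 0 sits at the genomic right end
        start, end = tx.length - end, tx.length - start
    off = 0
    for es, ee in tx.exons:
        el = ee - es
        s = max(start, off)
        e = min(end, off + el)
        if e > s:
            blocks.append((es + (s - off), es + (e - off)))
        off += el
    return blocks


def _blocks_to_cigar(blocks: list[tuple[int, int]]) -> list[tuple[str, int]]:
    cigar: list[tuple[str, int]] = []
    for i, (s, e) in enumerate(blocks):
        if i > 0:
            cigar.append(("N", s - blocks[i - 1][1]))
        cigar.append(("M", e - s))
    return cigar


def _apply_substitutions(
    seq: str, rate: float, rng: np.random.Generator
) -> tuple[str, int]:
    if rate <= 0:
        return seq, 0
    n = rng.binomial(len(seq), rate)
    if n == 0:
        return seq, 0
    positions = rng.choice(len(seq), size=n, replace=False)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    for p in positions:
        current = arr[p]
        options = _BASES[_BASES != current]
        arr[p] = options[rng.integers(0, len(options))]
    return arr.tobytes().decode(), int(n)


class _LibraryBuilder:
    def __init__(self, config, reference, transcripts, panel):
        config.validate()
        self.cfg = config
        self.ref = reference
        self.panel = panel
        self.rng = np.random.default_rng([config.seed, 2])
        self.records: list[AlignmentRecord] = []
        self.truth_rows: list[dict] = []

        txs = list(transcripts)
        self.coding = [
            t for t in txs if t.biotype == "protein_coding" and t.contig != "chrM"
        ]
        self.rrna = [t for t in txs if "rrna" in t.biotype.lower()]
        self.mito = [t for t in txs if t.contig == "chrM"]
        self.introns = [
            (t, s, e) for t in self.coding for s, e in t.introns
        ]
        self.gaps = self._intergenic_gaps(txs)
        # lognormal expression weights per source transcript, on their own
        # stream so replicate libraries can share one expression truth
        sigma = config.expression_dispersion
        wseed = config.seed if config.expression_seed is None else config.expression_seed
        wrng = np.random.default_rng([wseed, 3])
        self.weights = {
            t.transcript_id: float(w)
            for t, w in zip(
                sorted(txs, key=lambda t: t.transcript_id),
                wrng.lognormal(0.0, sigma, len(txs)),
            )
        }

    def _intergenic_gaps(self, txs):
        spans: dict[str, list[tuple[int, int]]] = {}
        for t in txs:
            spans.setdefault(t.contig, []).append((t.start, t.end))
        gaps = []
        margin = 200
        for contig, length in self.ref.lengths.items():
            ivs = sorted(spans.get(contig, []))
            prev = 0
            for s, e in ivs + [(length, length)]:
                if s - prev > 2 * margin + 700:
                    gaps.append((contig, prev + margin, s - margin))
                prev = max(prev, e)
        return gaps

    # -- sampling helpers ------------------------------------------------

    def _fragment_length(self, upper: int) -> int:
        cfg = self.cfg
        flen = int(round(self.rng.normal(cfg.fragment_mean, cfg.fragment_sd)))
        return max(cfg.read_length, min(flen, upper))

    def _choose_weighted(self, txs):
        w = np.array([self.weights[t.transcript_id] for t in txs])
        return txs[self.rng.choice(len(txs), p=w / w.sum())]

    def _biased_start(self, span: int) -> int:
        """Fragment start in transcript coordinates, 0 = 5' end."""
        if span <= 0:
            return 0
        b = self.cfg.three_prime_bias
        u = self.rng.random()
        if b <= 0:
            return int(u * (span + 1)) if span else 0
        x = math.log1p(u * math.expm1(b)) / b  # inverse CDF of exp(b*x) on [0,1]
        return min(span, int(x * (span + 1)))

    # -- emission ---------------------------------------------------------

    def _emit_mapped_pair(self, name, contig, blocks_a, blocks_b, rna_strand):
        """Write one aligned pair; returns per-copy substitution count."""
        cfg = self.cfg
        left, right = (
            (blocks_a, blocks_b)
            if blocks_a[0][0] <= blocks_b[0][0]
            else (blocks_b, blocks_a)
        )
        outer_start = left[0][0]
        outer_end = max(left[-1][1], right[-1][1])
        tlen = outer_end - outer_start

        if cfg.orientation == "unstranded":
            read1_is_right = self.rng.random() < 0.5
        elif cfg.orientation == "reverse":
            read1_is_right = rna_strand == "+"
        else:
            read1_is_right = rna_strand == "-"

        n_sub_total = 0
        recs = []
        for blocks, is_right in ((left, False), (right, True)):
            refseq = "".join(self.ref.sequences[contig][s:e] for s, e in blocks)
            seq, n_sub = _apply_substitutions(refseq, cfg.substitution_rate, self.rng)
            n_sub_total += n_sub
            quals = self.rng.integers(25, 41, len(seq)).tolist()
            is_read1 = is_right == read1_is_right
            mate = right if not is_right else left
            flags = FLAG_PAIRED | FLAG_PROPER_PAIR
            flags |= FLAG_READ1 if is_read1 else FLAG_READ2
            if is_right:
                flags |= FLAG_REVERSE
            else:
                flags |= FLAG_MATE_REVERSE
            recs.append(
                AlignmentRecord(
                    query_name=name,
                    flags=flags,
                    reference_name=contig,
                    position=blocks[0][0],
                    mapping_quality=60,
                    cigar=_blocks_to_cigar(blocks),
                    mate_reference_name=contig,
                    mate_position=mate[0][0],
                    template_length=tlen if not is_right else -tlen,
                    sequence=seq,
                    base_qualities=quals,
                )
            )
        self.records.extend(recs)
        return n_sub_total

    def _pcr_copies(self) -> int:
        m = self.cfg.duplication_mean_extra
        if m <= 0:
            return 1
        return int(self.rng.geometric(1.0 / (1.0 + m)))

    def _transcript_fragment(self, idx, category, txs):
        cfg = self.cfg
        tx = self._choose_weighted(txs)
        if tx.length < cfg.read_length:
            return None
        flen = self._fragment_length(tx.length)
        s = self._biased_start(tx.length - flen)
        read_a = _tx_interval_to_blocks(tx, s, s + cfg.read_length)
        read_b = _tx_interval_to_blocks(tx, s + flen - cfg.read_length, s + flen)
        sense = self.rng.random() >= cfg.antisense_rate
        rna_strand = tx.strand if sense else ("-" if tx.strand == "+" else "+")
        n_copies = self._pcr_copies()
        n_sub = 0
        for c in range(n_copies):
            n_sub += self._emit_mapped_pair(
                f"sim{idx:07d}c{c}", tx.contig, read_a, read_b, rna_strand
            )
        self.truth_rows.append(
            dict(
                fragment=f"sim{idx:07d}",
                category=category,
                source=tx.transcript_id,
                contig=tx.contig,
                rna_strand=rna_strand,
                sense=sense,
                start=s,
                length=flen,
                n_copies=n_copies,
                n_substitutions=n_sub,
                has_mapped=True,
                mapped_reads_per_copy=2,
            )
        )
        return True

    def _genomic_fragment(self, idx, category, contig, lo, hi, strand, source):
        cfg = self.cfg
        flen = self._fragment_length(hi - lo)
        if hi - lo < flen:
            return None
        s = int(self.rng.integers(lo, hi - flen + 1))
        read_a = [(s, s + cfg.read_length)]
        read_b = [(s + flen - cfg.read_length, s + flen)]
        sense = self.rng.random() >= cfg.antisense_rate
        rna_strand = strand if sense else ("-" if strand == "+" else "+")
        n_copies = self._pcr_copies()
        n_sub = 0
        for c in range(n_copies):
            n_sub += self._emit_mapped_pair(
                f"sim{idx:07d}c{c}", contig, read_a, read_b, rna_strand
            )
        self.truth_rows.append(
            dict(
                fragment=f"sim{idx:07d}",
                category=category,
                source=source,
                contig=contig,
                rna_strand=rna_strand,
                sense=sense,
                start=s,
                length=flen,
                n_copies=n_copies,
                n_substitutions=n_sub,
                has_mapped=True,
                mapped_reads_per_copy=2,
            )
        )
        return True

    def _spikein_fragment(self, idx):
        cfg = self.cfg
        panel = self.panel
        probs = np.array(
            [panel.concentrations[s] * panel.length(s) for s in panel.ids]
        )
        sid = panel.ids[self.rng.choice(len(panel.ids), p=probs / probs.sum())]
        seq = panel.sequences[sid]
        if len(seq) < cfg.read_length:
            return None
        flen = self._fragment_length(len(seq))
        s = int(self.rng.integers(0, len(seq) - flen + 1))
        fragment = seq[s : s + flen]
        read1_seq, n1 = _apply_substitutions(
            fragment[: cfg.read_length], cfg.substitution_rate, self.rng
        )
        from .io_model import reverse_complement

        read2_seq, n2 = _apply_substitutions(
            reverse_complement(fragment[-cfg.read_length :]),
            cfg.substitution_rate,
            self.rng,
        )
        name = f"sim{idx:07d}c0"
        half_mapped = self.rng.random() < cfg.spikein_half_mapped
        carrier = None
        if half_mapped and self.gaps:
            gi = int(self.rng.integers(0, len(self.gaps)))
            contig, lo, hi = self.gaps[gi]
            if hi - lo > cfg.read_length:
                pos = int(self.rng.integers(lo, hi - cfg.read_length))
                cseq, _ = _apply_substitutions(
                    self.ref.sequences[contig][pos : pos + cfg.read_length],
                    cfg.substitution_rate,
                    self.rng,
                )
                carrier = (contig, pos, cseq)
        if carrier is not None:
            contig, pos, cseq = carrier
            self.records.append(
                AlignmentRecord(
                    query_name=name,
                    flags=FLAG_PAIRED | FLAG_READ2 | FLAG_MATE_UNMAPPED,
                    reference_name=contig,
                    position=pos,
                    mapping_quality=60,
                    cigar=[("M", cfg.read_length)],
                    mate_reference_name=contig,
                    mate_position=pos,
                    template_length=0,
                    sequence=cseq,
                    base_qualities=self.rng.integers(25, 41, len(cseq)).tolist(),
                )
            )
            self.records.append(
                AlignmentRecord(
                    query_name=name,
                    flags=FLAG_PAIRED | FLAG_READ1 | FLAG_UNMAPPED,
                    reference_name=None,
                    position=None,
                    mapping_quality=0,
                    cigar=[],
                    mate_reference_name=contig,
                    mate_position=pos,
                    template_length=0,
                    sequence=read1_seq,
                    base_qualities=self.rng.integers(25, 41, len(read1_seq)).tolist(),
                )
            )
        else:
            base = FLAG_PAIRED | FLAG_UNMAPPED | FLAG_MATE_UNMAPPED
            for seq_i, flag_i in ((read1_seq, FLAG_READ1), (read2_seq, FLAG_READ2)):
                self.records.append(
                    AlignmentRecord(
                        query_name=name,
                        flags=base | flag_i,
                        reference_name=None,
                        position=None,
                        mapping_quality=0,
                        cigar=[],
                        mate_reference_name=None,
                        mate_position=None,
                        template_length=0,
                        sequence=seq_i,
                        base_qualities=self.rng.integers(25, 41, len(seq_i)).tolist(),
                    )
                )
        self.truth_rows.append(
            dict(
                fragment=f"sim{idx:07d}",
                category="spikein",
                source=sid,
                contig=carrier[0] if carrier else "*",
                rna_strand="+",
                sense=True,
                start=s,
                length=flen,
                n_copies=1,
                n_substitutions=n1 + (0 if carrier else n2),
                has_mapped=carrier is not None,
                mapped_reads_per_copy=1 if carrier else 0,
            )
        )
        return True

    # -- main loop ---------------------------------------------------------

    def build(self):
        cfg = self.cfg
        categories = ["exonic", "rrna", "mito", "intronic", "intergenic", "spikein"]
        fractions = np.array(
            [
                0.0,
                cfg.rrna_fraction,
                cfg.mito_fraction,
                cfg.intronic_fraction,
                cfg.intergenic_fraction,
                cfg.spikein_fraction,
            ]
        )
        fractions[0] = 1.0 - fractions.sum()
        draws = self.rng.choice(len(categories), size=cfg.n_fragments, p=fractions)
        flen_floor = int(cfg.fragment_mean + 4 * cfg.fragment_sd)
        eligible_introns = [
            (t, s, e) for (t, s, e) in self.introns if e - s >= flen_floor
        ]
        eligible_gaps = [
            (c, lo, hi) for (c, lo, hi) in self.gaps if hi - lo >= flen_floor
        ]
        skipped = 0
        for idx, d in enumerate(draws):
            cat = categories[d]
            ok = None
            if cat == "exonic":
                ok = self._transcript_fragment(idx, "exonic", self.coding)
            elif cat == "rrna":
                ok = self._transcript_fragment(idx, "rrna", self.rrna or self.coding)
            elif cat == "mito":
                ok = self._transcript_fragment(idx, "mito", self.mito or self.coding)
            elif cat == "intronic":
                if eligible_introns:
                    ti = int(self.rng.integers(0, len(eligible_introns)))
                    t, s, e = eligible_introns[ti]
                    ok = self._genomic_fragment(
                        idx, "intronic", t.contig, s, e, t.strand, t.transcript_id
                    )
            elif cat == "intergenic":
                if eligible_gaps:
                    gi = int(self.rng.integers(0, len(eligible_gaps)))
                    contig, lo, hi = eligible_gaps[gi]
                    strand = "+" if self.rng.random() < 0.5 else "-"
                    ok = self._genomic_fragment(
                        idx, "intergenic", contig, lo, hi, strand, "intergenic"
                    )
            else:
                ok = self._spikein_fragment(idx)
            if ok is None:
                skipped += 1

        order = {name: i for i, name in enumerate(self.ref.sequences)}
        self.records.sort(
            key=lambda r: (
                (order[r.reference_name], r.position, r.query_name, r.is_read1)
                if not r.is_unmapped
                else (len(order), 0, r.query_name, r.is_read1)
            )
        )
        truth = SimulationTruth(
            config=self.cfg,
            expression_weights=dict(self.weights),
            fragments=pd.DataFrame(
                self.truth_rows,
                columns=[
                    "fragment",
                    "category",
                    "source",
                    "contig",
                    "rna_strand",
                    "sense",
                    "start",
                    "length",
                    "n_copies",
                    "n_substitutions",
                    "has_mapped",
                    "mapped_reads_per_copy",
                ],
            ),
        )
        return self.records, truth


def simulate_library(
    config: SimulationConfig,
    reference: ReferenceSet,
    transcripts: list[TranscriptModel],
    panel: SpikeInPanel,
) -> tuple[list[AlignmentRecord], SimulationTruth]:
    """Draw a full paired-end library with per-fragment ground truth.

    Records come back coordinate-sorted (unmapped pairs last).  Identical
    config and inputs give byte-identical output files.
    """
    return _LibraryBuilder(config, reference, transcripts, panel).build()


def simulate_to_directory(config: SimulationConfig, out_dir: str | Path) -> dict:
    """Generate references + one library and write all artifacts as text.

    Writes genome.fa, annotation.gtf, spikeins.fa, spikeins.tsv, reads.sam,
    truth.tsv and config.yaml; returns the paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    reference, transcripts, panel = generate_reference_and_annotation(config)
    records, truth = simulate_library(config, reference, transcripts, panel)
    paths = {
        "genome": out / "genome.fa",
        "annotation": out / "annotation.gtf",
        "spikein_fasta": out / "spikeins.fa",
        "spikein_table": out / "spikeins.tsv",
        "alignments": out / "reads.sam",
        "truth": out / "truth.tsv",
        "config": out / "config.yaml",
    }
    reference.to_fasta(paths["genome"])
    write_gtf(transcripts, paths["annotation"])
    panel.to_files(paths["spikein_fasta"], paths["spikein_table"])
    write_alignments(records, paths["alignments"], reference.lengths)
    truth.to_tsv(paths["truth"])
    config.to_yaml(paths["config"])
    return {k: str(v) for k, v in paths.items()}
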