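"""Independent brute-force re-computation of every scalar library metric.

Deliberately shares no code with the package under test: SAM, GTF and
FASTA are parsed by hand from the written text files, intervals are plain
sorted lists scanned with linear/bisect passes, and flags are raw bit
masks.  Used as the oracle side of dual-route equivalence checks.
"""
from __future__ import annotations

import re
import statistics

PAIRED, PROPER, UNMAP, MUNMAP, REVERSE, MREVERSE, READ1, READ2, DUP = (
    0x1, 0x2, 0x4, 0x8, 0x10, 0x20, 0x40, 0x80, 0x400,
)

_CIGAR_RE = re.compile(r"(\d+)([MIDNS])")


def read_sam(path):
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("@"):
                continue
            f = line.rstrip("\n").split("\t")
            rows.append(
                dict(
                    name=f[0],
                    flag=int(f[1]),
                    contig=f[2],
                    pos=int(f[3]) - 1,
                    cigar=[(int(n), op) for n, op in _CIGAR_RE.findall(f[5])],
                    tlen=int(f[8]),
                    seq=f[9],
                    qual=f[10],
                )
            )
    return rows


def read_fasta(path):
    seqs, name, parts = {}, None, []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if name:
                    seqs[name] = "".join(parts)
                name, parts = line[1:].split()[0], []
            else:
                parts.append(line)
    if name:
        seqs[name] = "".join(parts)
    return seqs


def read_gtf(path):
    """Exon rows -> transcripts {tid: (contig, strand, gene, biotype, [exons])}."""
    txs = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if f[2] != "exon":
                continue
            attrs = dict(re.findall(r'(\w+) "([^"]*)"', f[8]))
            tid = attrs["transcript_id"]
            entry = txs.setdefault(
                tid,
                [f[0], f[6], attrs["gene_id"], attrs.get("gene_biotype", ""), []],
            )
            entry[4].append((int(f[3]) - 1, int(f[4])))
    for entry in txs.values():
        entry[4].sort()
    return txs


def merge(intervals):
    out = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def overlap_len(block, intervals):
    s, e = block
    return sum(max(0, min(e, ie) - max(s, is_)) for is_, ie in intervals)


def blocks_of(row):
    blocks, pos = [], row["pos"]
    for n, op in row["cigar"]:
        if op == "M":
            blocks.append((pos, pos + n))
            pos += n
        elif op in "DN":
            pos += n
    return blocks


def unclipped5(row):
    cigar = row["cigar"]
    if row["flag"] & REVERSE:
        end = row["pos"] + sum(n for n, op in cigar if op in "MDN")
        return end + (cigar[-1][0] if cigar and cigar[-1][1] == "S" else 0)
    return row["pos"] - (cigar[0][0] if cigar and cigar[0][1] == "S" else 0)


class Oracle:
    def __init__(self, sam_path, gtf_path, fasta_path, mito="chrM"):
        self.rows = read_sam(sam_path)
        self.txs = read_gtf(gtf_path)
        self.ref = read_fasta(fasta_path)
        self.mito = mito

        # per-contig merged exon unions, gene spans, per-gene exon lists
        self.exons_by_contig = {}
        self.genes_by_contig = {}
        self.gene_exons = {}
        self.gene_biotype = {}
        per_contig_exons, per_contig_genes = {}, {}
        gene_bounds = {}
        for contig, strand, gene, biotype, exons in self.txs.values():
            per_contig_exons.setdefault(contig, []).extend(exons)
            self.gene_exons.setdefault(gene, []).extend(exons)
            self.gene_biotype[gene] = biotype
            lo = min(s for s, _ in exons)
            hi = max(e for _, e in exons)
            if gene in gene_bounds:
                c0, l0, h0 = gene_bounds[gene]
                gene_bounds[gene] = (c0, min(l0, lo), max(h0, hi))
            else:
                gene_bounds[gene] = (contig, lo, hi)
        for contig, exons in per_contig_exons.items():
            self.exons_by_contig[contig] = merge(exons)
        for gene, (contig, lo, hi) in gene_bounds.items():
            per_contig_genes.setdefault(contig, []).append((lo, hi))
        self.genes_by_contig = {c: merge(v) for c, v in per_contig_genes.items()}
        self.gene_exons = {g: merge(v) for g, v in self.gene_exons.items()}
        self.gene_by_contig_list = {}
        for gene, (contig, lo, hi) in gene_bounds.items():
            self.gene_by_contig_list.setdefault(contig, []).append(gene)

        # junctions per (contig, donor, acceptor) -> set of strands
        self.junctions = {}
        for contig, strand, _g, _b, exons in self.txs.values():
            for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
                self.junctions.setdefault((contig, e1, s2), set()).add(strand)

        self.mark_duplicates()

    # -- duplicate marking (same contract, independent code) -------------
    def mark_duplicates(self):
        frags = {}
        for row in self.rows:
            frags.setdefault(row["name"], []).append(row)
        groups = {}
        for name, mates in frags.items():
            mapped = [m for m in mates if not m["flag"] & UNMAP]
            if not mapped:
                continue
            if len(mapped) == 2:
                r1 = next((m for m in mapped if m["flag"] & READ1), mapped[0])
                r2 = next(m for m in mapped if m is not r1)
                key = (
                    r1["contig"], unclipped5(r1), bool(r1["flag"] & REVERSE),
                    r2["contig"], unclipped5(r2), bool(r2["flag"] & REVERSE),
                )
            else:
                m = mapped[0]
                key = (m["contig"], unclipped5(m), bool(m["flag"] & REVERSE),
                       None, None, None)
            score = sum(ord(c) - 33 for m in mates for c in m["qual"])
            groups.setdefault(key, []).append((score, name))
        self.dup_names = set()
        self.fragments_total = 0
        for key, members in groups.items():
            self.fragments_total += len(members)
            if len(members) > 1:
                # highest summed base quality wins, ties to the first name
                keep = sorted(members, key=lambda t: (-t[0], t[1]))[0][1]
                self.dup_names.update(n for _s, n in members if n != keep)

    @property
    def duplicate_rate(self):
        return len(self.dup_names) / self.fragments_total

    def usable(self):
        for row in self.rows:
            if row["flag"] & UNMAP or row["name"] in self.dup_names:
                continue
            yield row

    # -- metrics -----------------------------------------------------------
    def totals(self):
        total = len(self.rows)
        mapped = sum(1 for r in self.rows if not r["flag"] & UNMAP)
        return total, mapped / total

    def categories(self):
        exonic = intronic = intergenic = mito = rrna = 0
        assigned = {}
        for row in self.usable():
            if row["contig"] == self.mito:
                mito += 1
            blocks = blocks_of(row)
            aligned = sum(e - s for s, e in blocks)
            exon_ov = sum(
                overlap_len(b, self.exons_by_contig.get(row["contig"], []))
                for b in blocks
            )
            gene_ov = sum(
                overlap_len(b, self.genes_by_contig.get(row["contig"], []))
                for b in blocks
            )
            if 2 * exon_ov >= aligned:
                exonic += 1
                per_gene = {}
                for gene in self.gene_by_contig_list.get(row["contig"], []):
                    ov = sum(overlap_len(b, self.gene_exons[gene]) for b in blocks)
                    if ov:
                        per_gene[gene] = ov
                if len(per_gene) == 1:
                    gene = next(iter(per_gene))
                    assigned[gene] = assigned.get(gene, 0) + 1
                    if "rrna" in self.gene_biotype[gene].lower():
                        rrna += 1
            elif 2 * gene_ov >= aligned:
                intronic += 1
            else:
                intergenic += 1
        classified = exonic + intronic + intergenic
        mapped_nondup = sum(1 for _ in self.usable())
        return dict(
            pct_exonic=exonic / classified,
            pct_intronic=intronic / classified,
            pct_intergenic=intergenic / classified,
            pct_mitochondrial=mito / mapped_nondup,
            pct_rRNA=rrna / mapped_nondup,
            intron_exon_ratio=intronic / exonic,
            genes_detected=sum(1 for c in assigned.values() if c >= 1),
            assigned=assigned,
        )

    def strand_specificity(self, min_overhang=3):
        sense, anti = {}, {}
        for row in self.usable():
            cigar = row["cigar"]
            if not any(op == "N" for _n, op in cigar):
                continue
            read_strand = "-" if row["flag"] & REVERSE else "+"
            if row["flag"] & READ1:  # dUTP: first-in-pair is antisense
                frag_strand = "+" if read_strand == "-" else "-"
            else:
                frag_strand = read_strand
            pos = row["pos"]
            for i, (n, op) in enumerate(cigar):
                if op == "N":
                    left = cigar[i - 1] if i > 0 else (0, "?")
                    right = cigar[i + 1] if i + 1 < len(cigar) else (0, "?")
                    if (
                        left[1] == "M"
                        and right[1] == "M"
                        and left[0] >= min_overhang
                        and right[0] >= min_overhang
                    ):
                        strands = self.junctions.get((row["contig"], pos, pos + n), ())
                        for jstrand in strands:
                            j = (row["contig"], pos, pos + n, jstrand)
                            if frag_strand == jstrand:
                                sense[j] = sense.get(j, 0) + 1
                            else:
                                anti[j] = anti.get(j, 0) + 1
                if op in "MDN":
                    pos += n
        observed = set(sense) | set(anti)
        clean = sum(1 for j in observed if j not in anti)
        return clean / len(observed), len(observed)

    def mismatches(self):
        n_bases = n_mm = 0
        for row in self.usable():
            ref = self.ref[row["contig"]]
            qpos, rpos = 0, row["pos"]
            for n, op in row["cigar"]:
                if op == "M":
                    for q, r in zip(row["seq"][qpos:qpos + n], ref[rpos:rpos + n]):
                        if r != "N":
                            n_bases += 1
                            if q != r:
                                n_mm += 1
                    qpos += n
                    rpos += n
                elif op in "IS":
                    qpos += n
                elif op in "DN":
                    rpos += n
        return n_mm, n_bases

    def insert_sizes(self, max_insert=2000):
        by_name = {}
        for row in self.usable():
            if (
                row["flag"] & PROPER
                and row["contig"] == self.mito
                and not any(op == "N" for _n, op in row["cigar"])
            ):
                by_name.setdefault(row["name"], []).append(row)
        sizes = []
        for mates in by_name.values():
            if len(mates) != 2:
                continue
            tlen = max(m["tlen"] for m in mates)
            if 0 < tlen <= max_insert:
                sizes.append(tlen)
        return sizes

    def insert_mean_sd(self):
        sizes = self.insert_sizes()
        return (
            statistics.fmean(sizes),
            statistics.stdev(sizes) if len(sizes) > 1 else 0.0,
            len(sizes),
        )
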