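"""Genomic-origin annotation of back-splice junctions.

Assigns each junction an origin class (CDS, UTR-CDS, UTR, intronic,
intergenic, two-gene), host gene(s), exon composition, circular spliced
sequence and a name, and computes summary feature statistics (size
distribution, most-upstream circularized exon, circRNAs per gene, exon
counts).

Class precedence:

1. acceptor end in an exon of one gene and donor end in an exon of a
   *different*, same-strand, adjacent gene (transcription-upstream gene
   first) -> two-gene;
2. both ends in exons of one gene -> CDS if every junction-bounded exonic
   nucleotide lies in the CDS, UTR if none does, else UTR-CDS;
3. within one gene's span but either end intronic -> intronic;
4. otherwise -> intergenic.

Junction/exon boundary matching requires exact coordinate equality.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections import Counter, defaultdict

import numpy as np
import pandas as pd

from .models import (BackspliceJunction, CircRecord, GeneModel, GenomeBundle,
                     revcomp)


@dataclass
class OriginCall:
    """Origin assignment for one junction."""

    origin: str
    host_genes: tuple[str, ...]
    acceptor_exon: int | None   # 1-based, transcription order
    donor_exon: int | None
    boundary_exact: bool
    exon_intervals: tuple[tuple[int, int], ...] = ()  # genomic, sorted


def _exon_at_start(gene: GeneModel, pos: int):
    """Exon interval containing pos as an internal/start coordinate."""
    for iv in gene.exons:
        if iv[0] <= pos < iv[1]:
            return iv
    return None


def _exon_at_end(gene: GeneModel, pos: int):
    """Exon interval containing pos as an (exclusive) end coordinate."""
    for iv in gene.exons:
        if iv[0] < pos <= iv[1]:
            return iv
    return None


def _adjacent(g1: GeneModel, g2: GeneModel, genes: list[GeneModel]) -> bool:
    """True if no other gene overlaps the interval between g1 and g2."""
    left, right = (g1, g2) if g1.start <= g2.start else (g2, g1)
    for g in genes:
        if g.gene_id in (g1.gene_id, g2.gene_id):
            continue
        if g.chrom == g1.chrom and g.start < right.start and g.end > left.end:
            return False
    return True


def _cds_class(gene: GeneModel, intervals) -> str:
    cov = tot = 0
    for a, b in intervals:
        tot += b - a
        for ca, cb in gene.cds_ranges:
            cov += max(0, min(b, cb) - max(a, ca))
    if cov == 0:
        return "UTR"
    return "CDS" if cov == tot else "UTR-CDS"


def assign_origin(junction: BackspliceJunction,
                  genes: list[GeneModel]) -> OriginCall:
    """Classify one junction against the gene models (see module rules)."""
    chrom_genes = [g for g in genes if g.chrom == junction.chrom]
    if not any(g.chrom == junction.chrom for g in genes) and genes:
        raise ValueError(f"no annotation for chromosome {junction.chrom}")
    same = [g for g in chrom_genes if g.strand == junction.strand]
    start, end = junction.start, junction.end

    start_hits = [(g, _exon_at_start(g, start)) for g in same]
    start_hits = [(g, iv) for g, iv in start_hits if iv]
    end_hits = [(g, _exon_at_end(g, end)) for g in same]
    end_hits = [(g, iv) for g, iv in end_hits if iv]

    def prefer(hits, boundary_pos, is_start):
        """Prefer the gene sharing the exact boundary, else longest overlap."""
        if len(hits) == 1:
            return hits[0]
        exact = [(g, iv) for g, iv in hits
                 if (iv[0] == boundary_pos if is_start else iv[1] == boundary_pos)]
        if exact:
            return exact[0]
        return max(hits, key=lambda h: min(h[1][1], end) - max(h[1][0], start))

    # rule 1: two-gene
    if start_hits and end_hits:
        gs, ivs = prefer(start_hits, start, True)
        ge, ive = prefer(end_hits, end, False)
        if gs.gene_id != ge.gene_id:
            if junction.strand == "+":
                up, dn = gs, ge
            else:
                up, dn = ge, gs
            upstream_ok = (up.start < dn.start) if junction.strand == "+" \
                else (up.start > dn.start)
            # transcription-upstream gene must come first along transcription
            if junction.strand == "-":
                upstream_ok = up.start > dn.start
            if upstream_ok and _adjacent(gs, ge, chrom_genes):
                exact = ivs[0] == start and ive[1] == end
                if junction.strand == "+":
                    acc = up.exon_index(ivs) if exact else None
                    don = dn.exon_index(ive) if exact else None
                else:
                    acc = up.exon_index(ive) if exact else None
                    don = dn.exon_index(ivs) if exact else None
                comp = _two_gene_intervals(up, dn, start, end,
                                           junction.strand) if exact else ()
                return OriginCall("two-gene", (up.gene_id, dn.gene_id),
                                  acc, don, exact, comp)
        else:
            # rule 2: single-gene exonic
            g = gs
            exact = ivs[0] == start and ive[1] == end
            inner = tuple(iv for iv in sorted(g.exons)
                          if iv[0] >= ivs[0] and iv[1] <= ive[1])
            clipped = tuple((max(a, start), min(b, end)) for a, b in inner
                            if max(a, start) < min(b, end))
            if g.strand == "+":
                acc_iv, don_iv = ivs, ive
            else:
                acc_iv, don_iv = ive, ivs
            return OriginCall(_cds_class(g, clipped), (g.gene_id,),
                              g.exon_index(acc_iv) if exact else None,
                              g.exon_index(don_iv) if exact else None,
                              exact, clipped if exact else ())

    # rule 3: intronic (within one gene's span, an end not exonic)
    for g in same:
        if g.start <= start and end <= g.end:
            return OriginCall("intronic", (g.gene_id,), None, None, False)

    return OriginCall("intergenic", (), None, None, False)


def _two_gene_intervals(up: GeneModel, dn: GeneModel, start: int, end: int,
                        strand: str) -> tuple[tuple[int, int], ...]:
    """Read-through composition: acceptor exon..last exon of the upstream
    gene plus exon 1..donor exon of the downstream gene."""
    if strand == "+":
        up_ivs = [iv for iv in up.exons if iv[0] >= start]
        dn_ivs = [iv for iv in dn.exons if iv[1] <= end]
    else:
        up_ivs = [iv for iv in up.exons if iv[1] <= end]
        dn_ivs = [iv for iv in dn.exons if iv[0] >= start]
    return tuple(sorted(up_ivs + dn_ivs))


def splice_circ_sequence(junction: BackspliceJunction, call: OriginCall,
                         genome: GenomeBundle) -> str:
    """Circular spliced sequence, 5'->3' on the transcribed strand.

    Boundary-exact records concatenate annotated exon sequences in
    transcription order; others fall back to the genomic interval
    [start, end) on the transcribed strand.
    """
    chrom = genome.sequences[junction.chrom]
    if call.boundary_exact and call.exon_intervals:
        ivs = sorted(call.exon_intervals)
        order = ivs if junction.strand == "+" else ivs[::-1]
        parts = [chrom[a:b] if junction.strand == "+" else revcomp(chrom[a:b])
                 for a, b in order]
        return "".join(parts)
    seg = chrom[junction.start:junction.end]
    return seg if junction.strand == "+" else revcomp(seg)


def _exon_composition(call: OriginCall,
                      genes_by_id: dict[str, GeneModel]
                      ) -> tuple[tuple[str, int], ...]:
    if not (call.boundary_exact and call.exon_intervals):
        return ()
    comp = []
    for iv in call.exon_intervals:
        for gid in call.host_genes:
            g = genes_by_id[gid]
            if tuple(iv) in g.exons:
                comp.append((gid, g.exon_index(iv)))
                break
    # order along the transcript: upstream-gene exons in transcription
    # order, then downstream-gene exons
    if len(call.host_genes) == 2:
        comp.sort(key=lambda t: (call.host_genes.index(t[0]), t[1]))
    else:
        comp.sort(key=lambda t: t[1])
    return tuple(comp)


def annotate_junctions(junctions: list[BackspliceJunction],
                       genome: GenomeBundle) -> list[CircRecord]:
    """Assign origin, sequence, composition and name to every junction."""
    genes_by_id = {g.gene_id: g for g in genome.genes}
    records = []
    for j in junctions:
        call = assign_origin(j, genome.genes)
        seq = splice_circ_sequence(j, call, genome)
        comp = _exon_composition(call, genes_by_id)
        records.append(CircRecord(j, call.origin, call.host_genes, comp,
                                  seq))
    return name_circrna(records)


def name_circrna(records: list[CircRecord]) -> list[CircRecord]:
    """Assign unique names.

    Single-gene: ``circ{GENE}_{n}`` with n the coordinate rank of the
    junction among that gene's junctions; two-gene:
    ``{GENE1}_e{i}:{GENE2}_e{j}`` from the acceptor exon of the upstream
    gene and the donor exon of the downstream gene; intergenic:
    ``circINTERGENIC_{chrom}_{start}``.
    """
    by_gene: dict[str, list[CircRecord]] = defaultdict(list)
    for r in records:
        if len(r.host_genes) == 1:
            by_gene[r.host_genes[0]].append(r)
    rank: dict[int, int] = {}
    for gid, recs in by_gene.items():
        for n, r in enumerate(sorted(
                recs, key=lambda r: (r.junction.start, r.junction.end)), 1):
            rank[id(r)] = n
    for r in records:
        if r.origin == "two-gene":
            g1, g2 = r.host_genes
            e1 = next((i for g, i in r.exon_composition if g == g1), 0)
            e2 = max((i for g, i in r.exon_composition if g == g2), default=0)
            r.name = f"{g1}_e{e1}:{g2}_e{e2}"
        elif len(r.host_genes) == 1:
            r.name = f"circ{r.host_genes[0]}_{rank[id(r)]}"
        else:
            r.name = (f"circINTERGENIC_{r.junction.chrom}_"
                      f"{r.junction.start}")
    names = [r.name for r in records]
    for name, cnt in Counter(names).items():
        if cnt > 1:   # disambiguate collisions deterministically
            k = 0
            for r in records:
                if r.name == name:
                    k += 1
                    if k > 1:
                        r.name = f"{name}.{k}"
    return records


def feature_stats(records: list[CircRecord],
                  genes: list[GeneModel]) -> dict[str, pd.DataFrame]:
    """Summary tables of circRNA features.

    Returns: ``size`` (spliced length and genomic span per circRNA),
    ``acceptor_exon`` (most-upstream circularized exon distribution),
    ``per_gene`` (circRNAs-per-gene distribution), ``by_gene_exons``
    (mean circRNAs per gene binned by gene exon count, bin width 10) and
    ``exons_per_circ`` (number of exons per circRNA distribution).
    """
    size = pd.DataFrame({
        "name": [r.name for r in records],
        "spliced_length": [r.spliced_length for r in records],
        "genomic_span": [r.junction.end - r.junction.start for r in records],
        "origin": [r.origin for r in records]})

    acc = Counter()
    nex = Counter()
    for r in records:
        if r.exon_composition:
            first_gene = r.host_genes[0]
            idx = [i for g, i in r.exon_composition if g == first_gene]
            acc[min(idx)] += 1
            nex[len(r.exon_composition)] += 1
    acceptor = pd.DataFrame(sorted(acc.items()),
                            columns=["exon_index", "n_circ"])
    exons_per_circ = pd.DataFrame(sorted(nex.items()),
                                  columns=["n_exons", "n_circ"])

    per_gene_counts = Counter()
    for r in records:
        for gid in r.host_genes:
            per_gene_counts[gid] += 1
    dist = Counter(per_gene_counts.values())
    per_gene = pd.DataFrame(sorted(dist.items()),
                            columns=["circ_per_gene", "n_genes"])

    rows = []
    for g in genes:
        b = (g.n_exons - 1) // 10
        rows.append({"gene_id": g.gene_id, "exon_bin": f"{b*10+1}-{b*10+10}",
                     "bin_order": b, "n_circ": per_gene_counts.get(g.gene_id, 0)})
    bg = pd.DataFrame(rows).groupby(["bin_order", "exon_bin"], as_index=False)[
        "n_circ"].mean().rename(columns={"n_circ": "mean_circ_per_gene"})
    return {"size": size, "acceptor_exon": acceptor,
            "per_gene": per_gene, "by_gene_exons": bg,
            "exons_per_circ": exons_per_circ}
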