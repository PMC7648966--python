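"""Readers and writers for the plain-text formats the pipeline touches.

FASTA/FASTQ go through Biopython; GTF is the minimal 9-column dialect the
toy annotation uses (gene/transcript/exon/CDS features with a ``gene_id``
attribute, 1-based inclusive coordinates converted to internal 0-based
half-open at this boundary); junctions are BED6 with the score column
carrying total unique back-spliced reads and a sidecar TSV for per-sample
support.  All readers round-trip their writers.
"""

from __future__ import annotations

import re
from collections import defaultdict
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import (BackspliceJunction, CountMatrix, FormatError, GeneModel,
                     GenomeBundle, VALID_BASES)


# ---------------------------------------------------------------- FASTA

def read_fasta(path) -> dict[str, str]:
    """Read FASTA into {name: uppercase sequence}; alphabet must be ACGTN."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - VALID_BASES
        if bad:
            raise FormatError(
                f"{path}: record {rec.id} contains non-nucleotide characters "
                f"{sorted(bad)}")
        out[rec.id] = seq
    return out


def write_fasta(sequences: dict[str, str], path, width: int = 70) -> None:
    recs = [SeqRecord(Seq(s), id=name, description="")
            for name, s in sequences.items()]
    with open(path, "w") as fh:
        SeqIO.write(recs, fh, "fasta")


# ---------------------------------------------------------------- GTF

_GTF_ATTR = re.compile(r'(\w+) "([^"]*)"')


def _parse_attrs(field: str) -> dict[str, str]:
    return dict(_GTF_ATTR.findall(field))


def read_gtf(path) -> list[GeneModel]:
    """Parse gene models from GTF (1-based inclusive -> 0-based half-open)."""
    exons: dict[str, list[tuple[int, int]]] = defaultdict(list)
    cds: dict[str, list[tuple[int, int]]] = defaultdict(list)
    meta: dict[str, tuple[str, str, str]] = {}
    order: list[str] = []
    for ln, line in enumerate(open(path), 1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 9:
            raise FormatError(f"{path}:{ln}: expected 9 tab fields")
        chrom, _src, feat, start, end, _score, strand, _frame, attrs = parts
        if feat not in ("gene", "transcript", "exon", "CDS"):
            continue
        a = _parse_attrs(attrs)
        gid = a.get("gene_id")
        if not gid:
            raise FormatError(f"{path}:{ln}: {feat} without gene_id")
        iv = (int(start) - 1, int(end))  # GTF 1-based inclusive -> half-open
        if iv[0] >= iv[1]:
            raise FormatError(f"{path}:{ln}: empty interval")
        if gid not in meta:
            meta[gid] = (chrom, strand, a.get("gene_biotype", "coding"))
            order.append(gid)
        if feat == "exon":
            exons[gid].append(iv)
        elif feat == "CDS":
            cds[gid].append(iv)
    genes = []
    for gid in order:
        chrom, strand, biotype = meta[gid]
        if not exons[gid]:
            continue
        ivs = sorted(exons[gid])
        if strand == "-":
            ivs = ivs[::-1]
        try:
            genes.append(GeneModel(gid, chrom, strand, tuple(ivs),
                                   tuple(sorted(cds[gid])), biotype))
        except ValueError as e:
            raise FormatError(f"{path}: {e}") from e
    return genes


def write_gtf(genes: list[GeneModel], path, source: str = "circheart") -> None:
    with open(path, "w") as fh:
        for g in genes:
            attr = f'gene_id "{g.gene_id}"; gene_biotype "{g.biotype}";'

            def row(feat, a, b):
                return (f"{g.chrom}\t{source}\t{feat}\t{a + 1}\t{b}\t.\t"
                        f"{g.strand}\t.\t{attr}\n")

            fh.write(row("gene", g.start, g.end))
            fh.write(row("transcript", g.start, g.end))
            for a, b in g.exons:
                fh.write(row("exon", a, b))
            for a, b in g.cds_ranges:
                fh.write(row("CDS", a, b))


# ---------------------------------------------------------------- BED6 junctions

def write_junction_bed(junctions: list[BackspliceJunction], path,
                       support_path=None) -> None:
    """BED6: chrom, start, end, name, score=total unique reads, strand.

    ``support_path`` (TSV) keeps the per-sample support that BED cannot hold.
    """
    with open(path, "w") as fh:
        for i, j in enumerate(junctions, 1):
            fh.write(f"{j.chrom}\t{j.start}\t{j.end}\tcirc_{i}\t"
                     f"{j.total_support}\t{j.strand}\n")
    if support_path is not None:
        samples = sorted({s for j in junctions for s in j.support})
        with open(support_path, "w") as fh:
            fh.write("chrom\tstart\tend\tstrand\t" + "\t".join(samples) + "\n")
            for j in junctions:
                row = [j.chrom, str(j.start), str(j.end), j.strand]
                row += [str(int(j.support.get(s, 0))) for s in samples]
                fh.write("\t".join(row) + "\n")


def read_junction_bed(path, support_path=None) -> list[BackspliceJunction]:
    support: dict[tuple, dict[str, int]] = {}
    if support_path is not None and Path(support_path).exists():
        df = pd.read_csv(support_path, sep="\t")
        samples = list(df.columns[4:])
        for _, r in df.iterrows():
            key = (r["chrom"], int(r["start"]), int(r["end"]), r["strand"])
            support[key] = {s: int(r[s]) for s in samples}
    out = []
    for ln, line in enumerate(open(path), 1):
        line = line.strip()
        if not line or line.startswith(("#", "track")):
            continue
        f = line.split("\t")
        if len(f) < 6:
            raise FormatError(f"{path}:{ln}: expected >= 6 BED fields")
        chrom, start, end, _name, score, strand = f[:6]
        start, end = int(start), int(end)
        if start >= end:
            raise FormatError(f"{path}:{ln}: start >= end")
        key = (chrom, start, end, strand)
        sup = support.get(key, {"all": int(score)} if int(score) else {})
        out.append(BackspliceJunction(chrom, start, end, strand, sup))
    return out


# ---------------------------------------------------------------- FASTQ

def read_fastq(path) -> list[tuple[str, str]]:
    """FASTQ -> list of (read_id, sequence); qualities are ignored."""
    return [(rec.id, str(rec.seq).upper())
            for rec in SeqIO.parse(str(path), "fastq")]


def write_fastq(reads: list[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


# ---------------------------------------------------------------- tables

def read_sample_sheet(path) -> dict[str, str]:
    """Two-column TSV (sample_id, group) -> mapping; header optional."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if list(df.iloc[0]) == ["sample_id", "group"]:
        df = df.iloc[1:]
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def write_sample_sheet(groups: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tgroup\n")
        for s, g in groups.items():
            fh.write(f"{s}\t{g}\n")


def write_count_matrix(matrix: CountMatrix, path) -> None:
    df = pd.DataFrame(matrix.counts, index=matrix.feature_ids,
                      columns=matrix.sample_ids)
    df.index.name = "feature_id"
    with open(path, "w") as fh:
        fh.write("#totals\t" + "\t".join(str(int(t)) for t in matrix.totals)
                 + "\n")
        fh.write("#groups\t" + "\t".join(matrix.groups[s]
                                         for s in matrix.sample_ids) + "\n")
        df.to_csv(fh, sep="\t")


def read_count_matrix(path) -> CountMatrix:
    with open(path) as fh:
        totals_line = fh.readline().rstrip("\n").split("\t")
        groups_line = fh.readline().rstrip("\n").split("\t")
        if totals_line[0] != "#totals" or groups_line[0] != "#groups":
            raise FormatError(f"{path}: missing #totals/#groups header")
        df = pd.read_csv(fh, sep="\t", index_col=0)
    totals = np.array([float(x) for x in totals_line[1:]])
    groups = dict(zip(df.columns, groups_line[1:]))
    return CountMatrix(list(df.index), list(df.columns),
                       df.to_numpy(dtype=np.int64), totals, groups)
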