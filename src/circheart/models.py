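"""Core data model and coordinate conventions.

All internal coordinates are 0-based half-open (BED convention) on the
forward genomic strand.  GTF input/output converts at the boundary.  A
back-splice junction is keyed by ``(chrom, start, end, strand)`` where
``start`` is the acceptor coordinate (5'-most genomic position of the
circle) and ``end`` the exclusive donor coordinate; ``start < end`` always,
regardless of strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

VALID_BASES = frozenset("ACGTN")

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (keeps case, maps N->N)."""
    return seq.translate(_COMP)[::-1]


class FormatError(ValueError):
    """Raised when an on-disk file violates its format contract."""


@dataclass(frozen=True)
class GeneModel:
    """A gene with one transcript model.

    ``exons`` are ``(start, end)`` half-open intervals in *transcription*
    order: ascending genomic coordinate on '+', descending on '-'.
    ``cds_ranges`` must be contained in the exon union; empty for
    noncoding genes.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_ranges: tuple[tuple[int, int], ...] = ()
    biotype: str = "coding"

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        ivs = sorted(self.exons)
        for (a, b) in ivs:
            if a >= b:
                raise ValueError(f"{self.gene_id}: empty exon ({a},{b})")
        for (a, b), (c, d) in zip(ivs, ivs[1:]):
            if b > c:
                raise ValueError(f"{self.gene_id}: overlapping exons")
        want = ivs if self.strand == "+" else ivs[::-1]
        if list(self.exons) != [tuple(x) for x in want]:
            raise ValueError(f"{self.gene_id}: exons not in transcription order")
        for (a, b) in self.cds_ranges:
            if not any(ea <= a and b <= eb for ea, eb in self.exons):
                raise ValueError(f"{self.gene_id}: CDS ({a},{b}) outside exons")

    @property
    def start(self) -> int:
        return min(a for a, _ in self.exons)

    @property
    def end(self) -> int:
        return max(b for _, b in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def exon_index(self, interval: tuple[int, int]) -> int:
        """1-based transcription-order index of an exon interval."""
        return self.exons.index(tuple(interval)) + 1

    def spliced_sequence(self, sequences: dict[str, str]) -> str:
        """cDNA: exon sequences concatenated in transcription order, 5'->3'."""
        chrom = sequences[self.chrom]
        parts = []
        for a, b in self.exons:
            s = chrom[a:b]
            parts.append(s if self.strand == "+" else revcomp(s))
        return "".join(parts)

    def exonic_length(self) -> int:
        return sum(b - a for a, b in self.exons)


@dataclass
class GenomeBundle:
    """Chromosome sequences plus gene models: the coordinate frame."""

    sequences: dict[str, str]
    genes: list[GeneModel] = field(default_factory=list)

    def validate(self) -> None:
        for name, seq in self.sequences.items():
            bad = set(seq) - VALID_BASES
            if bad:
                raise FormatError(f"{name}: non-nucleotide characters {sorted(bad)}")
        for g in self.genes:
            if g.chrom not in self.sequences:
                raise ValueError(f"{g.gene_id}: unknown chromosome {g.chrom}")
            if g.end > len(self.sequences[g.chrom]):
                raise ValueError(f"{g.gene_id}: exceeds chromosome length")

    def genes_by_chrom(self, chrom: str) -> list[GeneModel]:
        return sorted((g for g in self.genes if g.chrom == chrom),
                      key=lambda g: g.start)

    def gene(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)


@dataclass
class BackspliceJunction:
    """A back-splice junction with per-sample unique supporting-read counts."""

    chrom: str
    start: int
    end: int
    strand: str
    support: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"junction start {self.start} >= end {self.end}")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        for s, c in self.support.items():
            if c < 0 or int(c) != c:
                raise ValueError(f"support[{s}] = {c} not a non-negative integer")

    @property
    def key(self) -> tuple[str, int, int, str]:
        return (self.chrom, self.start, self.end, self.strand)

    @property
    def total_support(self) -> int:
        return int(sum(self.support.values()))

    def __hash__(self):
        return hash(self.key)

    def __eq__(self, other):
        return isinstance(other, BackspliceJunction) and self.key == other.key


@dataclass
class CircRecord:
    """An annotated circRNA."""

    junction: BackspliceJunction
    origin: str  # CDS | UTR-CDS | UTR | intronic | intergenic | two-gene
    host_genes: tuple[str, ...]
    exon_composition: tuple[tuple[str, int], ...]  # (gene_id, 1-based exon idx)
    spliced_seq: str
    name: str = ""

    def __post_init__(self):
        if (self.origin == "two-gene") != (len(self.host_genes) == 2):
            raise ValueError("origin 'two-gene' iff two host genes")

    @property
    def spliced_length(self) -> int:
        return len(self.spliced_seq)


@dataclass
class CountMatrix:
    """Features x samples integer counts with per-sample depth and groups.

    ``totals`` are total mapped reads (SRPBM denominator) or total fragments
    (FPKM denominator); ``groups`` maps each sample id to a group label.
    """

    feature_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    totals: np.ndarray
    groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        self.totals = np.asarray(self.totals, dtype=float)
        if self.counts.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError("counts shape does not match feature_ids x sample_ids")
        if self.totals.shape != (len(self.sample_ids),):
            raise ValueError("totals length does not match sample_ids")
        if np.any(self.totals <= 0):
            raise ValueError("totals must be positive")

    def group_labels(self) -> list[str]:
        """Group labels in first-appearance order (reference group first)."""
        return list(dict.fromkeys(self.groups[s] for s in self.sample_ids))

    def samples_of(self, group: str) -> list[int]:
        return [i for i, s in enumerate(self.sample_ids) if self.groups[s] == group]

    def subset(self, feature_ids: list[str]) -> "CountMatrix":
        idx = [self.feature_ids.index(f) for f in feature_ids]
        return CountMatrix(list(feature_ids), list(self.sample_ids),
                           self.counts[idx], self.totals, dict(self.groups))
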