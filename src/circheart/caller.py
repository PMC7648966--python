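"""Anchor-based back-splice junction detection.

A simplified find_circ-style caller: reads that fail to align contiguously
are split into two terminal k-mer anchors (default k=20) which are placed
on the genome independently.  If both anchors place uniquely on one
chromosome and strand, and the anchor from the read *start* lands
downstream of the anchor from the read *end* (reversed orientation), the
two anchor alignments are extended toward the read interior until the
whole read is explained by two genomic segments whose joint breakpoint is
flanked by the canonical splice signal (AG immediately 5' of the acceptor
segment, GT immediately 3' of the donor segment, on the transcribed
strand).  Junctions are reported as 0-based half-open [start, end) on the
forward strand with start = acceptor coordinate and end = donor
coordinate.

Anchor placement is exact-match by default; a ``mm`` knob allows
mismatches in anchor placement (breakpoint extension stays exact).
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np

from .models import BackspliceJunction, GenomeBundle, revcomp


@dataclass
class AnchorIndex:
    """Exact k-mer -> occurrence lookup over both genome strands.

    Occurrences are ``(chrom, strand, pos)`` with ``pos`` in strand-local
    coordinates (position within the reverse-complemented sequence for
    '-').  A k-mer is *unique* iff it has exactly one occurrence in the
    whole index; N-containing k-mers are not indexed.
    """

    k: int
    lookup: dict[str, list[tuple[str, str, int]]]
    strand_seqs: dict[tuple[str, str], str]

    def occurrences(self, kmer: str) -> list[tuple[str, str, int]]:
        return self.lookup.get(kmer, [])

    def unique_occurrence(self, kmer: str):
        occ = self.occurrences(kmer)
        return occ[0] if len(occ) == 1 else None


def build_index(genome: GenomeBundle, k: int = 20) -> AnchorIndex:
    """Index every genomic k-mer of both strands."""
    if k < 4:
        raise ValueError("anchor length k must be >= 4")
    if any(len(s) < k for s in genome.sequences.values()):
        raise ValueError("k larger than shortest chromosome")
    lookup: dict[str, list] = defaultdict(list)
    strand_seqs: dict[tuple[str, str], str] = {}
    for chrom, seq in genome.sequences.items():
        for strand, s in (("+", seq), ("-", revcomp(seq))):
            strand_seqs[(chrom, strand)] = s
            for p in range(len(s) - k + 1):
                kmer = s[p:p + k]
                if "N" not in kmer:
                    lookup[kmer].append((chrom, strand, p))
    return AnchorIndex(k, dict(lookup), strand_seqs)


def _scan_mm(text_u8: np.ndarray, pattern: str, mm: int) -> list[int]:
    """All start positions where pattern matches with <= mm mismatches."""
    pat = np.frombuffer(pattern.encode(), dtype=np.uint8)
    win = np.lib.stride_tricks.sliding_window_view(text_u8, len(pat))
    d = (win != pat).sum(axis=1)
    return np.nonzero(d <= mm)[0].tolist()


def _anchor_occurrences(index: AnchorIndex, kmer: str, mm: int,
                        u8_cache: dict) -> list[tuple[str, str, int]]:
    if mm == 0:
        return index.occurrences(kmer)
    occ = []
    for (chrom, strand), s in index.strand_seqs.items():
        key = (chrom, strand)
        if key not in u8_cache:
            u8_cache[key] = np.frombuffer(s.encode(), dtype=np.uint8)
        for p in _scan_mm(u8_cache[key], kmer, mm):
            occ.append((chrom, strand, p))
    return occ


# ------------------------------------------------------------------ linear

def align_linear(reads: list[tuple[str, str]], index: AnchorIndex,
                 genome: GenomeBundle, mm: int = 0
                 ) -> tuple[int, list[tuple[str, str]]]:
    """Toy contiguous aligner standing in for genome-wide read mapping.

    A read is *mapped* iff its full length matches the genome (either
    strand) with <= mm mismatches, or matches an annotated spliced
    transcript sequence exactly.  Returns (mapped_count, unmapped_reads).
    Reads shorter than 2k are skipped (cannot form two anchors) and are
    neither mapped nor returned.
    """
    texts = [s for s in genome.sequences.values()]
    texts += [revcomp(s) for s in genome.sequences.values()]
    texts += [g.spliced_sequence(genome.sequences) for g in genome.genes]
    haystack = "#".join(texts)
    u8 = np.frombuffer(haystack.encode(), dtype=np.uint8) if mm else None
    mapped = 0
    unmapped: list[tuple[str, str]] = []
    for rid, seq in reads:
        if len(seq) < 2 * index.k:
            continue
        if seq in haystack:
            mapped += 1
        elif mm and _scan_mm(u8, seq, mm):
            mapped += 1
        else:
            unmapped.append((rid, seq))
    return mapped, unmapped


# ------------------------------------------------------------------ calls

@dataclass
class CandidateCall:
    """Back-splice evidence from a single read."""

    read_id: str
    read_seq: str
    chrom: str
    start: int      # forward-strand acceptor coordinate (0-based)
    end: int        # forward-strand donor coordinate (exclusive)
    strand: str
    acceptor_pos: int   # strand-local acceptor segment start
    donor_pos: int      # strand-local donor segment end
    splice_signal: str = "GT/AG"

    @property
    def key(self):
        return (self.chrom, self.start, self.end, self.strand)


@dataclass
class CallStats:
    """Drop counters for auditability of the caller's silent drops."""

    total: int = 0
    called: int = 0
    dropped: Counter = field(default_factory=Counter)


def _common_prefix_len(a: str, b: str) -> int:
    n = min(len(a), len(b))
    i = 0
    while i < n and a[i] == b[i]:
        i += 1
    return i


def call_backsplice(reads: list[tuple[str, str]], index: AnchorIndex,
                    genome: GenomeBundle, mm: int = 0,
                    require_signal: bool = True,
                    stats: CallStats | None = None) -> list[CandidateCall]:
    """Emit one CandidateCall per read explained by a back-splice.

    Drops (silently, counted in ``stats``): reads with non-unique or
    unplaceable anchors, anchors on different chromosomes/strands,
    forward-ordered anchors (ordinary linear splice), and reads with no
    signal-consistent breakpoint.  Among signal-consistent breakpoints the
    one maximizing the acceptor-segment length is chosen (then the
    smallest start coordinate).
    """
    k = index.k
    stats = stats if stats is not None else CallStats()
    u8_cache: dict = {}
    out = []
    for rid, seq in reads:
        stats.total += 1
        L = len(seq)
        if L < 2 * k:
            stats.dropped["too_short"] += 1
            continue
        occA = _anchor_occurrences(index, seq[:k], mm, u8_cache)
        occB = _anchor_occurrences(index, seq[-k:], mm, u8_cache)
        if len(occA) != 1 or len(occB) != 1:
            stats.dropped["anchor_not_unique"] += 1
            continue
        (chromA, strandA, pA), (chromB, strandB, pB) = occA[0], occB[0]
        if chromA != chromB or strandA != strandB:
            stats.dropped["anchors_discordant"] += 1
            continue
        if pA <= pB:
            stats.dropped["forward_order"] += 1
            continue
        W = index.strand_seqs[(chromA, strandA)]
        extA = _common_prefix_len(seq, W[pA:pA + L])
        tail = W[max(0, pB + k - L):pB + k]
        extB = _common_prefix_len(seq[::-1], tail[::-1])
        best = None
        for s in range(max(k, L - extB), min(extA, L - k) + 1):
            acc = pB + k - (L - s)       # acceptor segment start
            dend = pA + s                # donor segment end (exclusive)
            if acc <= 0 or dend >= len(W) - 1 or acc >= dend:
                continue
            if require_signal and not (W[acc - 2:acc] == "AG"
                                       and W[dend:dend + 2] == "GT"):
                continue
            best = (s, acc, dend)
            break   # smallest s = longest acceptor segment
        if best is None:
            stats.dropped["no_breakpoint"] += 1
            continue
        _s, acc, dend = best
        if strandA == "+":
            start, end = acc, dend
        else:
            Lc = len(genome.sequences[chromA])
            start, end = Lc - dend, Lc - acc
        out.append(CandidateCall(rid, seq, chromA, start, end, strandA,
                                 acc, dend))
        stats.called += 1
    return out


def aggregate_junctions(calls_per_sample: dict[str, list[CandidateCall]],
                        min_reads: int = 2) -> list[BackspliceJunction]:
    """Group calls by junction key; count distinct read sequences.

    Support per sample = number of distinct supporting read *sequences*
    (exact duplicates collapse).  Junctions are kept iff support >=
    ``min_reads`` in at least one sample; output sorted by key.
    """
    seqs: dict[tuple, dict[str, set]] = defaultdict(lambda: defaultdict(set))
    for sample, calls in calls_per_sample.items():
        for c in calls:
            seqs[c.key][sample].add(c.read_seq)
    out = []
    for key in sorted(seqs):
        support = {s: len(v) for s, v in seqs[key].items()}
        if max(support.values()) >= min_reads:
            chrom, start, end, strand = key
            out.append(BackspliceJunction(chrom, start, end, strand, support))
    return out


def call_sample_junctions(reads_by_sample: dict[str, list[tuple[str, str]]],
                          genome: GenomeBundle, k: int = 20, mm: int = 0,
                          min_reads: int = 2, require_signal: bool = True
                          ) -> tuple[list[BackspliceJunction], dict, dict]:
    """Full per-sample detection: linear alignment, anchor calling,
    aggregation.  Returns (junctions, mapped_totals, stats_by_sample)."""
    index = build_index(genome, k)
    calls: dict[str, list[CandidateCall]] = {}
    totals: dict[str, int] = {}
    stats: dict[str, CallStats] = {}
    for sample, reads in reads_by_sample.items():
        mapped, unmapped = align_linear(reads, index, genome, mm=mm)
        st = CallStats()
        calls[sample] = call_backsplice(unmapped, index, genome, mm=mm,
                                        require_signal=require_signal,
                                        stats=st)
        totals[sample] = mapped
        stats[sample] = st
    junctions = aggregate_junctions(calls, min_reads=min_reads)
    return junctions, totals, stats
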