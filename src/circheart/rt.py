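"""Read-through circRNA vs homology-artifact classification.

A circRNA whose junction joins exons of two adjacent same-strand genes is
either a true read-through (rt-)circRNA or an artifact of read
misalignment between highly similar neighboring genes.  The decision
rule: take the 50-bp flanks on each side of the back-splice junction
(from the circular spliced sequence, transcribed strand) and align each
against the cDNA of both candidate host genes.  If either flank aligns to
*both* genes, the junction is a likely homology artifact; if each flank
hits only its expected host gene, the circRNA is a true rt-circRNA.

Alignment is Smith-Waterman local alignment (match +1, mismatch -2, gap
open -5, gap extend -2; both orientations tried); a *hit* requires
identity >= 0.8 over an aligned length >= 25 by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from Bio import Align

from .models import CircRecord, GenomeBundle, revcomp


@dataclass
class FlankPair:
    """Junction flanks from the circular sequence.

    ``donor_flank``: last w nt before the back-splice (suffix of the
    spliced sequence); ``acceptor_flank``: first w nt after it (prefix).
    If the circle is shorter than 2w the whole sequence is split at the
    junction.
    """

    donor_flank: str
    acceptor_flank: str
    w: int = 50


@dataclass
class HomologyHit:
    query: str        # 'donor_flank' | 'acceptor_flank'
    subject_gene: str
    score: float
    identity: float
    aligned_length: int


@dataclass
class RtCall:
    circ_name: str
    call: str         # 'true_rt' | 'homology_artifact'
    hits: list[HomologyHit] = field(default_factory=list)
    low_evidence: bool = False


def extract_flanks(record: CircRecord, w: int = 50) -> FlankPair:
    """Flanks of the back-splice junction on the circular sequence."""
    seq = record.spliced_seq
    if not seq:
        raise ValueError(f"{record.name}: empty spliced sequence")
    if len(seq) < 2 * w:
        half = len(seq) // 2
        return FlankPair(seq[len(seq) - half:], seq[:len(seq) - half], w)
    return FlankPair(seq[-w:], seq[:w], w)


def _aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "local"
    al.match_score = 1
    al.mismatch_score = -2
    al.open_gap_score = -5      # first gap base
    al.extend_gap_score = -2    # each further base
    return al


def local_align(query: str, subject: str) -> tuple[float, float, int]:
    """Best Smith-Waterman local alignment of query vs subject.

    Both query orientations are tried.  Returns (score, identity,
    aligned_length) of the best-scoring alignment; identity is matches /
    aligned columns (gap columns count against identity).
    """
    if not query or not subject:
        raise ValueError("empty sequence")
    al = _aligner()
    best = (0.0, 0.0, 0)
    for q in (query, revcomp(query)):
        score = al.score(q, subject)
        if score <= 0 or score <= best[0]:
            continue
        aln = al.align(q, subject)[0]
        matches = sum(1 for a, b in zip(aln[0], aln[1])
                      if a == b and a != "-")
        length = len(aln[0])
        best = (float(score), matches / length if length else 0.0, length)
    return best


def _hits(flank: str, gene_id: str, cdnas: list[str],
          min_identity: float, min_length: int, label: str
          ) -> list[HomologyHit]:
    out = []
    for cdna in cdnas:
        score, ident, length = local_align(flank, cdna)
        if ident >= min_identity and length >= min_length:
            out.append(HomologyHit(label, gene_id, score, ident, length))
    return out


def classify_two_gene(record: CircRecord, flanks: FlankPair,
                      cdna1: list[str], cdna2: list[str],
                      min_identity: float = 0.8,
                      min_length: int = 25) -> RtCall:
    """Apply the flank-homology decision rule to one two-gene record.

    ``cdna1``: transcript sequences of the upstream host gene (the donor
    flank's expected origin is ambiguous in general, so both flanks are
    aligned against both genes).  Either flank hitting both genes ->
    homology_artifact; otherwise true_rt (with a low-evidence warning if
    a flank hits neither gene).
    """
    if not cdna1 or not cdna2:
        raise ValueError(f"{record.name}: missing host cDNA")
    g1, g2 = record.host_genes
    all_hits: list[HomologyHit] = []
    both = False
    neither = False
    for label, flank in (("donor_flank", flanks.donor_flank),
                         ("acceptor_flank", flanks.acceptor_flank)):
        h1 = _hits(flank, g1, cdna1, min_identity, min_length, label)
        h2 = _hits(flank, g2, cdna2, min_identity, min_length, label)
        all_hits += h1 + h2
        if h1 and h2:
            both = True
        if not h1 and not h2:
            neither = True
    call = "homology_artifact" if both else "true_rt"
    return RtCall(record.name, call, all_hits,
                  low_evidence=(not both and neither))


def screen_all(records: list[CircRecord], genome: GenomeBundle,
               flank: int = 50, min_identity: float = 0.8,
               min_length: int = 25) -> pd.DataFrame:
    """Classify every two-gene record; returns the rt-call table."""
    rows = []
    for r in records:
        if r.origin != "two-gene":
            continue
        fl = extract_flanks(r, flank)
        g1, g2 = (genome.gene(g) for g in r.host_genes)
        cd1 = [g1.spliced_sequence(genome.sequences)]
        cd2 = [g2.spliced_sequence(genome.sequences)]
        call = classify_two_gene(r, fl, cd1, cd2, min_identity, min_length)
        best = {("donor_flank", r.host_genes[0]): None,
                ("donor_flank", r.host_genes[1]): None,
                ("acceptor_flank", r.host_genes[0]): None,
                ("acceptor_flank", r.host_genes[1]): None}
        for h in call.hits:
            k = (h.query, h.subject_gene)
            if best.get(k) is None or h.score > best[k].score:
                best[k] = h
        rows.append({
            "name": r.name, "gene1": r.host_genes[0],
            "gene2": r.host_genes[1], "call": call.call,
            "low_evidence": call.low_evidence,
            **{f"{q}_hits_{g}": (round(h.identity, 3) if h else 0.0)
               for (q, g), h in best.items()}})
    return pd.DataFrame(rows)
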