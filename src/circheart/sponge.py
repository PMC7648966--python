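"""miRNA seed-match site counting on circular sequences and the
circRNA-miRNA-mRNA network.

Canonical site types against a miRNA seed (nucleotides 2-8 of the mature
sequence): with S = reverse complement of the seed (7 nt, pairs miRNA
positions 8..2), a target site is

* 8mer     = S followed by A,
* 7mer-m8  = S,
* 7mer-A1  = S[1:] followed by A (pairs positions 7..2, A opposite pos 1),
* 6mer     = S[1:].

Because the molecule is circular, sites may wrap the back-splice
junction; scanning uses the sequence extended by its first
(max site length - 1) nucleotides, with start positions reported modulo
the circle length.  Each start position yields at most one site, of its
most specific type (8mer > 7mer-m8 > 7mer-A1 > 6mer).  6mers are excluded
from default counts (weakest canonical type) and included via a flag.

Candidate rule: a circRNA is a sponge candidate iff it has at least
``min_sites`` (default 5) sites for at least one miRNA; the top tier
requires at least ``top_sites`` (default 10).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .models import revcomp

SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1", "6mer")

_RNA2DNA = str.maketrans("Uu", "Tt")
_VALID_SEED = frozenset("ACGU")


@dataclass(frozen=True)
class MiRNA:
    """A mature miRNA; ``seed`` = nucleotides 2-8 (RNA, 5'->3')."""

    id: str
    mature: str

    def __post_init__(self):
        if len(self.mature) < 8:
            raise ValueError(f"{self.id}: mature sequence shorter than 8 nt")
        if set(self.seed) - _VALID_SEED:
            raise ValueError(f"{self.id}: seed contains non-ACGU characters")

    @property
    def seed(self) -> str:
        return self.mature[1:8].replace("T", "U")

    def site_patterns(self) -> dict[str, str]:
        """DNA patterns on the target, keyed by site type."""
        S = revcomp(self.seed.translate(_RNA2DNA))
        return {"8mer": S + "A", "7mer-m8": S,
                "7mer-A1": S[1:] + "A", "6mer": S[1:]}


@dataclass(frozen=True)
class SiteHit:
    circ_id: str
    mirna_id: str
    site_type: str
    start: int      # position on the circular sequence (may wrap)


def circular_scan_sequence(spliced_seq: str, max_site_len: int = 8) -> str:
    """Sequence extended across the back-splice for pattern scanning.

    Appends the first ``max_site_len - 1`` nt (capped at the sequence
    length) so every wrapping site occurs contiguously; valid start
    positions are 0..len-1, mapping back modulo the circle length.
    """
    if not spliced_seq:
        raise ValueError("empty sequence")
    return spliced_seq + spliced_seq[:max_site_len - 1]


def seed_sites(spliced_seq: str, mirna: MiRNA,
               include_6mer: bool = False,
               circ_id: str = "") -> list[SiteHit]:
    """All seed-match sites of one miRNA on one circular sequence.

    DNA input is transliterated from RNA if needed.  Every start position
    on the circle is tested against the type patterns in specificity
    order; the first (most specific) match wins, so no start is counted
    twice.
    """
    seq = spliced_seq.upper().translate(_RNA2DNA)
    pats = mirna.site_patterns()
    types = SITE_TYPES if include_6mer else SITE_TYPES[:3]
    scan = circular_scan_sequence(seq)
    L = len(seq)
    # locate each pattern with str.find, then resolve per-start precedence
    best: dict[int, str] = {}
    for t in reversed(types):          # most specific type written last
        pat = pats[t]
        p = scan.find(pat)
        while p != -1:
            if p < L:
                best[p] = t
            p = scan.find(pat, p + 1)
    return [SiteHit(circ_id, mirna.id, best[p], p) for p in sorted(best)]


def site_count_table(circ_seqs: dict[str, str], mirnas: list[MiRNA],
                     include_6mer: bool = False) -> pd.DataFrame:
    """Long-format site counts per (circ, miRNA, site type), plus totals."""
    rows = []
    for cid, seq in circ_seqs.items():
        for m in mirnas:
            hits = seed_sites(seq, m, include_6mer, circ_id=cid)
            counts = {t: 0 for t in SITE_TYPES}
            for h in hits:
                counts[h.site_type] += 1
            rows.append({"circ": cid, "mirna": m.id, **counts,
                         "total": len(hits)})
    return pd.DataFrame(rows)


def sponge_candidates(sites: pd.DataFrame, min_sites: int = 5,
                      top_sites: int = 10
                      ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Candidate and top-tier sponge circRNAs from the site-count table.

    Returns (pair_matrix, candidates, top) where pair_matrix is circs x
    miRNAs total site counts, and the tier tables list circRNAs whose
    best miRNA reaches the threshold.
    """
    mat = sites.pivot_table(index="circ", columns="mirna", values="total",
                            fill_value=0, aggfunc="sum")
    best = mat.max(axis=1)
    cands = pd.DataFrame({"circ": mat.index, "max_sites": best.to_numpy(),
                          "best_mirna": mat.idxmax(axis=1).to_numpy()})
    candidates = cands[cands.max_sites >= min_sites].reset_index(drop=True)
    top = cands[cands.max_sites >= top_sites].reset_index(drop=True)
    return mat, candidates, top


def build_network(sites: pd.DataFrame, candidates: pd.DataFrame,
                  mirna_targets: pd.DataFrame,
                  gene_de: pd.DataFrame | None = None,
                  min_sites: int = 5) -> tuple[nx.DiGraph, pd.DataFrame]:
    """circRNA-miRNA-mRNA edge list (Cytoscape-importable) and graph.

    circ-miR edges connect candidates to each miRNA with >= min_sites
    sites (weight = site count); miR-mRNA edges come from the provided
    target table, annotated with the target's differential direction
    when a gene DE table is given.  miRNAs in the target table but absent
    from the site table are skipped with a warning column in mind
    (returned edge list simply omits them).
    """
    de_dir = {}
    if gene_de is not None:
        de_dir = dict(zip(gene_de["feature_id"], gene_de["direction"]))
    G = nx.DiGraph()
    edges = []
    cand_set = set(candidates["circ"])
    known_mirnas = set(sites["mirna"])
    pair = sites.groupby(["circ", "mirna"])["total"].sum()
    for (c, m), w in pair.items():
        if c in cand_set and w >= min_sites:
            G.add_edge(c, m, kind="circ-miR", weight=int(w))
            edges.append({"source": c, "target": m,
                          "interaction": "circ-miR", "weight": int(w),
                          "target_regulation": ""})
    for r in mirna_targets.itertuples():
        if r.mirna not in known_mirnas:
            continue
        if r.mirna not in G:
            continue
        reg = de_dir.get(r.gene, "ns")
        G.add_edge(r.mirna, r.gene, kind="miR-mRNA", weight=1,
                   regulation=reg)
        edges.append({"source": r.mirna, "target": r.gene,
                      "interaction": "miR-mRNA", "weight": 1,
                      "target_regulation": reg})
    return G, pd.DataFrame(edges, columns=["source", "target", "interaction",
                                           "weight", "target_regulation"])


def release_of_repression(edges: pd.DataFrame,
                          circ_de: pd.DataFrame) -> pd.DataFrame:
    """Descriptive report: miRNA targets that are down-regulated while
    their sponging circRNA is also down-regulated (de-repression
    pattern; no causal claim)."""
    circ_dir = dict(zip(circ_de["feature_id"], circ_de["direction"]))
    cm = edges[edges.interaction == "circ-miR"]
    mt = edges[(edges.interaction == "miR-mRNA")
               & (edges.target_regulation == "down")]
    rows = []
    for r in cm.itertuples():
        if circ_dir.get(r.source) != "down":
            continue
        for t in mt[mt.source == r.target].itertuples():
            rows.append({"circ": r.source, "mirna": r.target,
                         "gene": t.target})
    return pd.DataFrame(rows, columns=["circ", "mirna", "gene"])
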