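"""Junction-set comparison across studies on a shared coordinate frame.

Junctions are matched by exact canonical key (chrom, start, end[, strand]);
an optional slack window allows +/-N fuzzy matching for cross-pipeline
comparison.  Inputs must already share one genome assembly: no coordinate
lifting is performed here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import pandas as pd

from .models import BackspliceJunction


@dataclass
class JunctionSet:
    label: str
    keys: set[tuple] = field(default_factory=set)

    @classmethod
    def from_junctions(cls, label: str,
                       junctions: list[BackspliceJunction],
                       strand_aware: bool = True) -> "JunctionSet":
        return cls(label, {canonical_key(j, strand_aware)
                           for j in junctions})


def canonical_key(junction: BackspliceJunction,
                  strand_aware: bool = True) -> tuple:
    """(chrom, start, end, strand) or (chrom, start, end)."""
    if strand_aware:
        return (junction.chrom, junction.start, junction.end,
                junction.strand)
    return (junction.chrom, junction.start, junction.end)


def _match_with_slack(key: tuple, keys: set[tuple], slack: int) -> bool:
    if slack == 0:
        return key in keys
    chrom, start, end = key[0], key[1], key[2]
    rest = key[3:]
    for ds in range(-slack, slack + 1):
        for de in range(-slack, slack + 1):
            if (chrom, start + ds, end + de, *rest) in keys:
                return True
    return False


def overlap_sets(sets: list[JunctionSet], slack: int = 0) -> pd.DataFrame:
    """Venn-region counts for 2-5 junction sets.

    Returns one row per non-empty membership pattern (2^n - 1 regions)
    with the count of union elements whose membership matches exactly,
    plus per-set totals and the union size as attributes in extra rows
    is avoided: totals are derivable (sum of regions containing the set).
    With ``slack`` > 0 membership is +/-slack fuzzy and regions are
    computed over the union of observed keys (each key counted once).
    """
    if not 2 <= len(sets) <= 5:
        raise ValueError("overlap_sets supports 2-5 sets")
    union = set()
    for s in sets:
        union |= s.keys
    rows = []
    counts: dict[tuple, int] = {}
    for key in union:
        member = tuple(
            (key in s.keys) if slack == 0 else
            _match_with_slack(key, s.keys, slack)
            for s in sets)
        counts[member] = counts.get(member, 0) + 1
    n = len(sets)
    for mask in range(1, 2 ** n):
        member = tuple(bool(mask & (1 << i)) for i in range(n))
        rows.append({
            "region": "&".join(s.label for s, m in zip(sets, member) if m),
            **{s.label: m for s, m in zip(sets, member)},
            "count": counts.get(member, 0)})
    df = pd.DataFrame(rows)
    df.attrs["union"] = len(union)
    df.attrs["set_sizes"] = {s.label: len(s.keys) for s in sets}
    return df


def pairwise_overlap(sets: list[JunctionSet]) -> pd.DataFrame:
    """Pairwise intersection counts for any number of sets."""
    rows = []
    for a, b in combinations(sets, 2):
        rows.append({"set_a": a.label, "set_b": b.label,
                     "size_a": len(a.keys), "size_b": len(b.keys),
                     "intersection": len(a.keys & b.keys),
                     "union": len(a.keys | b.keys)})
    return pd.DataFrame(rows)
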