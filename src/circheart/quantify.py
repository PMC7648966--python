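"""Normalization, confidence tiers and circRNA-host-gene correlation.

circRNA abundance is normalized to SRPBM (spliced reads per billion
mapped reads): count x 1e9 / total mapped reads.  Linear gene expression
uses FPKM: count x 1e9 / (exon length x total fragments).  Two detection
tiers: *detected* = >= 2 unique back-spliced reads in at least one sample
(applied at junction aggregation), *high-confidence* = >= 2 unique reads
in at least 4 samples of at least one group.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .models import CountMatrix, GeneModel


def srpbm(count: float, total_mapped: float) -> float:
    """Spliced Reads Per Billion Mapped reads."""
    if total_mapped <= 0:
        raise ValueError("total_mapped must be positive")
    return count * 1e9 / total_mapped


def fpkm(count: float, exon_length: float, total_fragments: float) -> float:
    """Fragments Per Kilobase of exon per Million fragments mapped."""
    if exon_length <= 0 or total_fragments <= 0:
        raise ValueError("exon_length and total_fragments must be positive")
    return count * 1e9 / (exon_length * total_fragments)


def srpbm_table(matrix: CountMatrix) -> pd.DataFrame:
    """Per-sample SRPBM for every feature of a back-splice count matrix."""
    vals = matrix.counts * 1e9 / matrix.totals[None, :]
    return pd.DataFrame(vals, index=matrix.feature_ids,
                        columns=matrix.sample_ids)


def fpkm_table(matrix: CountMatrix, genes: list[GeneModel]) -> pd.DataFrame:
    """Per-sample FPKM; gene exon length = union of the gene's exons."""
    lengths = {g.gene_id: g.exonic_length() for g in genes}
    L = np.array([lengths[f] for f in matrix.feature_ids], dtype=float)
    vals = matrix.counts * 1e9 / (L[:, None] * matrix.totals[None, :])
    return pd.DataFrame(vals, index=matrix.feature_ids,
                        columns=matrix.sample_ids)


def tier_filter(matrix: CountMatrix, min_reads: int = 2,
                min_samples: int = 4) -> list[str]:
    """High-confidence features: count >= min_reads in >= min_samples
    samples of at least one group."""
    groups = matrix.group_labels()
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    keep = []
    for gi, grp in enumerate(groups):
        cols = matrix.samples_of(grp)
        if len(cols) < min_samples:
            raise ValueError(
                f"group {grp} has fewer than {min_samples} samples")
    ok = np.zeros(len(matrix.feature_ids), dtype=bool)
    for grp in groups:
        cols = matrix.samples_of(grp)
        n_det = (matrix.counts[:, cols] >= min_reads).sum(axis=1)
        ok |= n_det >= min_samples
    return [f for f, k in zip(matrix.feature_ids, ok) if k]


def presence_profile(matrix: CountMatrix, min_reads: int = 2) -> pd.Series:
    """Histogram over 0..n_samples of the number of samples in which each
    feature is detected (count >= min_reads)."""
    det = (matrix.counts >= min_reads).sum(axis=1)
    n = len(matrix.sample_ids)
    hist = np.bincount(det, minlength=n + 1)
    return pd.Series(hist, index=range(n + 1), name="n_features")


def host_correlation(circ_expr: pd.DataFrame, gene_expr: pd.DataFrame,
                     pairs: dict[str, str], n_random: int = 50,
                     seed: int = 0) -> dict:
    """Pearson correlation of circRNA vs host-gene expression.

    For each (circ, host) pair, Pearson r and two-sided p across samples;
    additionally ``n_random`` (circ, random non-host gene) pairs are drawn
    without replacement per circ.  The two r distributions are compared by
    a two-sided Wilcoxon rank-sum test.  Zero-variance features are
    excluded and reported.
    """
    rng = np.random.default_rng(seed)
    samples = list(circ_expr.columns)
    if len(samples) < 3:
        raise ValueError("need at least 3 samples")

    def usable(df, f):
        return f in df.index and np.std(df.loc[f].to_numpy()) > 0

    excluded = [c for c, g in pairs.items()
                if not (usable(circ_expr, c) and usable(gene_expr, g))]
    host_rows = []
    for c, g in pairs.items():
        if c in excluded:
            continue
        r, p = stats.pearsonr(circ_expr.loc[c, samples],
                              gene_expr.loc[g, samples])
        host_rows.append({"circ": c, "gene": g, "kind": "host",
                          "r": r, "p": p})
    if not host_rows:
        raise ValueError("all features zero-variance")

    genes = [g for g in gene_expr.index
             if np.std(gene_expr.loc[g].to_numpy()) > 0]
    circs = [row["circ"] for row in host_rows]
    random_rows = []
    k = 0
    while len(random_rows) < n_random:
        c = circs[k % len(circs)]
        k += 1
        candidates = [g for g in genes if g != pairs[c]]
        g = candidates[rng.integers(0, len(candidates))]
        r, p = stats.pearsonr(circ_expr.loc[c, samples],
                              gene_expr.loc[g, samples])
        random_rows.append({"circ": c, "gene": g, "kind": "random",
                            "r": r, "p": p})
    table = pd.DataFrame(host_rows + random_rows)
    host_r = table.loc[table.kind == "host", "r"]
    rand_r = table.loc[table.kind == "random", "r"]
    stat, pval = stats.ranksums(host_r, rand_r)
    return {"table": table, "excluded": excluded,
            "ranksum_stat": float(stat), "ranksum_p": float(pval),
            "mean_r_host": float(host_r.mean()),
            "mean_r_random": float(rand_r.mean())}
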