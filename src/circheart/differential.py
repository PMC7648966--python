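"""Two-group differential expression via a negative-binomial exact test.

The model: counts for feature i in group g are NB with mean mu_ig and a
common dispersion phi (variance mu + phi mu^2).  After notionally
equalizing library sizes, group sums are NB (sum of n iid NB(mu, phi) is
NB with mean n mu and size n/phi).  Conditional on the total t =
sum_A + sum_B under equal group means, the two-sided exact p-value is the
total probability of all splits (a, t-a) whose probability does not
exceed that of the observed split.  phi = 0 reduces to the binomial split
with proportion n_A / (n_A + n_B).

Significance rules mirror the asymmetric conventions of circRNA studies:
circRNAs use raw p < alpha and |FC| > threshold; the linear-gene track
uses Benjamini-Hochberg FDR < alpha and |FC| > threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .models import CountMatrix

PHI_FLOOR = 1e-6


@dataclass
class DispersionEstimate:
    phi: float
    method: str = "pooled-moments-median"


def estimate_dispersion(matrix: CountMatrix) -> DispersionEstimate:
    """Common NB dispersion by pooled method-of-moments.

    Counts are scaled to the mean library size; per feature, the
    within-group moment estimate phi_i = max(0, (s2_i - m_i) / m_i^2) is
    pooled across the two groups (weighted by degrees of freedom); the
    common phi is the median over features with mean >= 1, floored at
    1e-6.
    """
    groups = matrix.group_labels()
    scaled = matrix.counts * (matrix.totals.mean() / matrix.totals)[None, :]
    phis = []
    means = scaled.mean(axis=1)
    num = np.zeros(len(matrix.feature_ids))
    den = 0.0
    for grp in groups:
        cols = matrix.samples_of(grp)
        if len(cols) < 2:
            raise ValueError("need >= 2 samples per group")
        sub = scaled[:, cols]
        m = sub.mean(axis=1)
        s2 = sub.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            phi_g = np.where(m > 0, (s2 - m) / np.maximum(m, 1e-12) ** 2, 0.0)
        w = len(cols) - 1
        num += np.maximum(phi_g, 0.0) * w
        den += w
    phi_i = num / den
    ok = means >= 1
    if not np.any(ok):
        raise ValueError("no feature with mean count >= 1")
    phi = float(np.median(phi_i[ok]))
    return DispersionEstimate(max(phi, PHI_FLOOR))


def nb_exact_test(counts_a: np.ndarray, counts_b: np.ndarray, phi: float,
                  library_sizes: np.ndarray | None = None) -> float:
    """Conditional NB exact test of equal group means; two-sided.

    ``library_sizes`` (per sample, groups A then B) are used to equalize
    counts to the common (mean) library size before summing.
    """
    counts_a = np.asarray(counts_a, dtype=float)
    counts_b = np.asarray(counts_b, dtype=float)
    na, nb = len(counts_a), len(counts_b)
    if library_sizes is not None:
        lib = np.asarray(library_sizes, dtype=float)
        f = lib.mean() / lib
        counts_a = counts_a * f[:na]
        counts_b = counts_b * f[na:]
    sa = int(np.rint(counts_a.sum()))
    sb = int(np.rint(counts_b.sum()))
    t = sa + sb
    if t == 0:
        return 1.0
    a = np.arange(t + 1)
    if phi <= PHI_FLOOR:
        logp = stats.binom.logpmf(a, t, na / (na + nb))
    else:
        mu = t / (na + nb)          # fitted per-sample mean under the null
        ra, rb = na / phi, nb / phi
        p = 1.0 / (1.0 + phi * mu)  # same success prob for both group sums
        logp = (stats.nbinom.logpmf(a, ra, p)
                + stats.nbinom.logpmf(t - a, rb, p))
    m = logp.max()
    prob = np.exp(logp - m)
    prob /= prob.sum()              # conditional distribution of the split
    if prob[sa] >= prob.max() * (1 - 1e-12):
        return 1.0                  # observed split is modal
    pval = float(prob[prob <= prob[sa] * (1 + 1e-9)].sum())
    return min(pval, 1.0)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR, returned in input order.

    q_(i) = min_{j >= i} p_(j) * m / j over the ascending-sorted
    p-values, clipped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def de_table(matrix: CountMatrix, phi: float | None = None,
             fc_threshold: float = 2.0, alpha: float = 0.05,
             significance: str = "pvalue") -> pd.DataFrame:
    """Exact-test differential expression for all features.

    Fold change is computed from library-size-normalized group means with
    a pseudocount of 0.5 (testing never uses the pseudocount).  The
    second group (first-appearance order; the disease-like group when the
    sample sheet lists controls first) is the numerator.  ``significance``
    selects the rule: 'pvalue' (circRNA convention, raw p) or 'fdr'
    (linear-gene convention, BH-adjusted).
    """
    groups = matrix.group_labels()
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    ga, gb = groups
    ca, cb = matrix.samples_of(ga), matrix.samples_of(gb)
    if phi is None:
        phi = estimate_dispersion(matrix).phi
    lib = matrix.totals
    f = lib.mean() / lib
    norm = matrix.counts * f[None, :]
    mean_a = norm[:, ca].mean(axis=1)
    mean_b = norm[:, cb].mean(axis=1)
    log2fc = np.log2((mean_b + 0.5) / (mean_a + 0.5))
    pvals = np.array([
        nb_exact_test(matrix.counts[i, ca], matrix.counts[i, cb], phi,
                      library_sizes=np.concatenate([lib[ca], lib[cb]]))
        for i in range(len(matrix.feature_ids))])
    fdr = bh_adjust(pvals)
    crit = fdr if significance == "fdr" else pvals
    sig = (crit < alpha) & (np.abs(log2fc) > np.log2(fc_threshold))
    direction = np.where(~sig, "ns", np.where(log2fc > 0, "up", "down"))
    out = pd.DataFrame({
        "feature_id": matrix.feature_ids,
        f"mean_{ga}": mean_a, f"mean_{gb}": mean_b,
        "log2fc": log2fc, "pvalue": pvals, "fdr": fdr,
        "direction": direction, "phi": phi})
    return out.sort_values("pvalue", kind="mergesort").reset_index(drop=True)
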