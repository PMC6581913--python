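"""Shared statistical utilities.

Small wrappers around scipy/statsmodels with the edge-case conventions used
throughout the scans (two-tailed Z against zero, tie-corrected Mann-Whitney,
Pearson chi-square on a 2x2 table without continuity correction,
Benjamini-Hochberg step-up adjustment with missing-value pass-through), plus
an exact test of Hardy-Weinberg proportions for biallelic genotype counts.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "z_test_two_tailed",
    "mann_whitney_u",
    "chi2_2x2",
    "bh_fdr",
    "hwe_exact_p",
]


def z_test_two_tailed(value: float, se: float) -> float:
    """Two-tailed P for ``value`` against zero given a standard error.

    P = 2 * Phi(-|value/se|).  Degenerate SEs follow the limit convention:
    se = 0 with a nonzero value gives P = 0 (infinitely precise estimate
    away from zero); se = 0 with value = 0 gives P = 1.
    """
    if np.isnan(value) or np.isnan(se):
        return float("nan")
    if se < 0:
        raise ValueError("standard error must be non-negative")
    if se == 0:
        return 1.0 if value == 0 else 0.0
    return float(2.0 * sps.norm.sf(abs(value) / se))


def mann_whitney_u(xs, ys) -> float:
    """Two-sided Mann-Whitney U test P value.

    Exact enumeration when both samples have n <= 8 and no ties span the
    pooled data; otherwise the normal approximation with tie correction.
    Fully tied data (every value identical) returns P = 1.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.size == 0 or ys.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([xs, ys])
    if np.all(pooled == pooled[0]):
        return 1.0
    if xs.size <= 8 and ys.size <= 8 and np.unique(pooled).size == pooled.size:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(xs, ys, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))


def chi2_2x2(table) -> float:
    """Pearson chi-square P (df=1, no continuity correction) for a 2x2 table.

    Any zero margin makes the statistic undefined: returns NaN.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("table must be 2x2 with non-negative counts")
    row = t.sum(axis=1)
    col = t.sum(axis=0)
    if np.any(row == 0) or np.any(col == 0):
        return float("nan")
    n = t.sum()
    stat = n * (t[0, 0] * t[1, 1] - t[0, 1] * t[1, 0]) ** 2 / (
        row[0] * row[1] * col[0] * col[1]
    )
    return float(sps.chi2.sf(stat, df=1))


def bh_fdr(ps) -> np.ndarray:
    """Benjamini-Hochberg adjusted P values, order-preserving.

    NaN entries are passed through unchanged and do not count toward the
    number of tests m.
    """
    ps = np.asarray(ps, dtype=float)
    out = np.full(ps.shape, np.nan)
    ok = ~np.isnan(ps)
    if ok.sum() == 0:
        return out
    if np.any((ps[ok] < 0) | (ps[ok] > 1)):
        raise ValueError("P values must lie in [0, 1]")
    out[ok] = multipletests(ps[ok], method="fdr_bh")[1]
    return out


def hwe_exact_p(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact two-sided test of Hardy-Weinberg proportions.

    Enumerates every heterozygote count compatible with the observed allele
    counts and sums the probabilities of all configurations no more likely
    than the observed one (probability-ordering two-sided test).  Monomorphic
    samples (no copies of one allele) return P = 1: the test is undefined and
    the site passes.
    """
    n_hom_ref, n_het, n_hom_alt = int(n_hom_ref), int(n_het), int(n_hom_alt)
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    n_rare = 2 * min(n_hom_ref, n_hom_alt) + n_het  # copies of the minor allele
    if n == 0 or n_rare == 0 or n_rare == 2 * n:
        return 1.0

    # log-probability of each possible het count conditional on allele counts
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    logs = np.array(
        [
            _log_hwe_weight(n, n_rare, int(h))
            for h in hets
        ]
    )
    logs -= logs.max()
    probs = np.exp(logs)
    probs /= probs.sum()
    obs_het = n_het
    p_obs = probs[hets == obs_het][0]
    # small tolerance so equal-probability configurations are included
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def _log_hwe_weight(n: int, n_rare: int, n_het: int) -> float:
    """Log of the unnormalized conditional probability of a het count."""
    n_hom_rare = (n_rare - n_het) // 2
    n_hom_common = n - n_het - n_hom_rare
    if n_hom_rare < 0 or n_hom_common < 0:
        return -math.inf
    # P(h | allele counts) is proportional to 2^h * n! / (h! * n_hom_rare! * n_hom_common!)
    return (
        n_het * math.log(2.0)
        + math.lgamma(n + 1)
        - math.lgamma(n_het + 1)
        - math.lgamma(n_hom_rare + 1)
        - math.lgamma(n_hom_common + 1)
    )
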