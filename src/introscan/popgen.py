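"""Diversity and differentiation statistics on a SiteTable.

theta_pi (pairwise diversity), theta_w (Watterson's estimator), the
Weir-Cockerham F_ST estimator, absolute divergence d_XY, and the
generation-scaled mutation-rate helper mu = D * g / 2T.

Denominator convention: all per-site statistics are averaged over ``L``
sites.  For SNP-only transcriptome data L defaults to the number of usable
SNP sites in scope ("per-SNP" values); passing the surveyed length in bp
yields per-bp values.  Both conventions are exposed because SNP tables do not
record monomorphic sites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import SiteTable

__all__ = [
    "DiversityRecord",
    "DivergenceRecord",
    "theta_pi",
    "theta_w",
    "fst_wc",
    "fst_wc_components",
    "dxy",
    "dxy_per_site",
    "mutation_rate",
    "harmonic_number",
]


@dataclass
class DiversityRecord:
    group: str
    scope: str
    L: int
    S: int
    theta_pi: float
    theta_w: float


@dataclass
class DivergenceRecord:
    pair: tuple[str, str]
    scope: str
    dxy: float
    fst: float


def harmonic_number(n: int) -> float:
    """a_n = sum_{i=1}^{n-1} 1/i, the Watterson normalizer for n alleles."""
    if n < 2:
        raise ValueError("need at least two alleles")
    return float(np.sum(1.0 / np.arange(1, n)))


def _scope_sites(st: SiteTable, sites) -> np.ndarray:
    if sites is None:
        return np.arange(st.n_sites)
    return np.asarray(sites)


def theta_pi(
    st: SiteTable, group: str, sites=None, L: int | None = None,
    scope: str = "transcriptome",
) -> DiversityRecord:
    """Pairwise nucleotide diversity.

    Per site with k derived copies among n called alleles the expected
    heterozygosity of a random sequence pair is 2 k (n - k) / (n (n - 1));
    summed over sites and divided by L.  Sites with n < 2 are skipped.
    """
    idx = _scope_sites(st, sites)
    k, n = st.counts(group)
    k, n = k[idx].astype(float), n[idx].astype(float)
    ok = n >= 2
    k, n = k[ok], n[ok]
    if L is None:
        L = int(ok.sum())
    if L == 0:
        raise ValueError("no sites surveyed (L = 0)")
    het = 2.0 * k * (n - k) / (n * (n - 1.0))
    S = int(((k > 0) & (k < n)).sum())
    pi = float(het.sum() / L)
    return DiversityRecord(group=group, scope=scope, L=L, S=S,
                           theta_pi=pi, theta_w=_watterson(k, n, L))


def _watterson(k: np.ndarray, n: np.ndarray, L: int) -> float:
    # per-site 1/a_n for segregating sites, averaged over L; sites keep their
    # own call count n (variable-missingness convention)
    seg = (k > 0) & (k < n)
    if not seg.any():
        return 0.0
    ns = n[seg].astype(int)
    inv_a = np.array([1.0 / harmonic_number(m) for m in ns])
    return float(inv_a.sum() / L)


def theta_w(
    st: SiteTable, group: str, sites=None, L: int | None = None,
    scope: str = "transcriptome",
) -> DiversityRecord:
    """Watterson's estimator S / (a_n L), computed per site with each site's
    own called-allele count and averaged (see module docstring)."""
    return theta_pi(st, group, sites=sites, L=L, scope=scope)


def fst_wc_components(
    k1: np.ndarray, n1: np.ndarray, k2: np.ndarray, n2: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site Weir-Cockerham variance components for two populations.

    Alleles are the sampled units (allele-count data): with sample sizes
    n_i alleles and frequencies p_i, the among-population mean square is
    MSB = sum n_i (p_i - pbar)^2 / (r - 1) and the within-population mean
    square is MSW = sum n_i p_i (1 - p_i) / (n - r).  The estimator is
    (MSB - MSW) / (MSB + (n_c - 1) MSW) with n_c = n - sum n_i^2 / n, and
    multi-site values are ratios of summed components (ratio-of-sums).
    Returns per-site (numerator, denominator); both NaN where undefined.
    """
    k1 = np.asarray(k1, float); n1 = np.asarray(n1, float)
    k2 = np.asarray(k2, float); n2 = np.asarray(n2, float)
    n = n1 + n2
    usable = (n1 >= 2) & (n2 >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = k1 / n1
        p2 = k2 / n2
        pbar = (k1 + k2) / n
        msb = n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2
        msw = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / (n - 2)
        nc = n - (n1 ** 2 + n2 ** 2) / n
        num = msb - msw
        den = msb + (nc - 1) * msw
    num = np.where(usable, num, np.nan)
    den = np.where(usable, den, np.nan)
    return num, den


def fst_wc(
    st: SiteTable, group_a: str, group_b: str, sites=None,
    scope: str = "transcriptome",
) -> DivergenceRecord:
    """Weir-Cockerham F_ST between two groups over the scoped sites."""
    idx = _scope_sites(st, sites)
    k1, n1 = st.counts(group_a)
    k2, n2 = st.counts(group_b)
    num, den = fst_wc_components(k1[idx], n1[idx], k2[idx], n2[idx])
    ok = ~np.isnan(num)
    if not ok.any() or np.nansum(den) == 0:
        fst = float("nan")
    else:
        fst = float(np.nansum(num) / np.nansum(den))
    d = dxy(st, group_a, group_b, sites=sites, scope=scope).dxy
    return DivergenceRecord(pair=(group_a, group_b), scope=scope, dxy=d, fst=fst)


def dxy_per_site(st: SiteTable, group_a: str, group_b: str, sites=None) -> np.ndarray:
    """Per-site absolute divergence p_A (1 - p_B) + p_B (1 - p_A); NaN where
    either group has no called alleles."""
    idx = _scope_sites(st, sites)
    pa = st.freq(group_a)[idx]
    pb = st.freq(group_b)[idx]
    return pa * (1 - pb) + pb * (1 - pa)


def dxy(
    st: SiteTable, group_a: str, group_b: str, sites=None, L: int | None = None,
    scope: str = "transcriptome",
) -> DivergenceRecord:
    """Mean pairwise sequence divergence between two groups over L sites."""
    d = dxy_per_site(st, group_a, group_b, sites=sites)
    ok = ~np.isnan(d)
    if L is None:
        L = int(ok.sum())
    val = float(d[ok].sum() / L) if L > 0 else float("nan")
    return DivergenceRecord(pair=(group_a, group_b), scope=scope,
                            dxy=val, fst=float("nan"))


def mutation_rate(d_div: float, g: float, t: float) -> float:
    """Per-site per-generation mutation rate mu = D * g / (2 T).

    D is the observed pairwise inter-species difference frequency per site,
    g the generation time (years), T the divergence time (years).
    """
    if d_div <= 0 or g <= 0 or t <= 0:
        raise ValueError("all mutation-rate inputs must be strictly positive")
    return d_div * g / (2.0 * t)
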