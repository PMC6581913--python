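"""Per-unigene introgression scan: Patterson's D, f_dM, moving-block
bootstrap standard errors, Z-tests, and the multi-criterion candidate screen.

The quartet (P1, P2, P3, O) is: P1 a control population related to the
recipient, P2 the putative recipient, P3 the putative donor, O one or more
outgroups pooled into a single derived-allele frequency.  With derived
frequencies p1..p4 at a site,

    ABBA = (1 - p1) p2 p3 (1 - p4)
    BABA = p1 (1 - p2) p3 (1 - p4)
    D    = sum(ABBA - BABA) / sum(ABBA + BABA)

f_dM uses the same numerator S = sum(ABBA - BABA) but a dynamic denominator:
at each site the donor proxy P_D is the population with the higher derived
frequency (P2 vs P3 when p2 >= p1, else P1 vs P3), and the denominator term
substitutes P_D into both donor-like slots, negated on the p2 < p1 branch.
This bounds f_dM in [-1, 1] and makes it symmetric for introgression into P1
or P2.

Standard errors come from a moving-block bootstrap along the unigene: one
block starts at every site's position and spans ``block_bp``; a replicate
draws blocks uniformly with replacement until it covers at least as many
sites as the original gene, then recomputes the statistic.

A unigene is called introgressed only if D >= d_min, the BH-adjusted
Z-test P values of both D and f_dM fall below alpha, its donor-recipient
d_XY lies below the transcriptome mean, and the Mann-Whitney comparison of
its 200-bp-block d_XY values against the transcriptome-wide block
distribution is BH-significant.  Genes with d_XY at or above the mean are
rejected without testing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import PopulationMap, SiteTable, unigene_index
from .popgen import dxy_per_site
from .stats import bh_fdr, mann_whitney_u, z_test_two_tailed

logger = logging.getLogger(__name__)

__all__ = [
    "QuartetSpec",
    "ScanResult",
    "d_statistic",
    "f_dm",
    "site_terms",
    "moving_blocks",
    "block_bootstrap_se",
    "scan_unigenes",
    "screen_introgressed",
]


@dataclass
class QuartetSpec:
    """The four roles of the ABBA-BABA quartet; ``outgroups`` are pooled."""

    p1: str
    p2: str
    p3: str
    outgroups: list[str]

    @classmethod
    def from_popmap(cls, popmap: PopulationMap) -> "QuartetSpec":
        roles = popmap.roles
        return cls(
            p1=roles["control"],
            p2=roles["recipient"],
            p3=roles["donor"],
            outgroups=popmap.polarize_outgroups(),
        )

    def frequencies(self, st: SiteTable, sites=None):
        """Per-site derived frequencies (p1, p2, p3, p4) and usable mask."""
        idx = np.arange(st.n_sites) if sites is None else np.asarray(sites)
        p1 = st.freq(self.p1)[idx]
        p2 = st.freq(self.p2)[idx]
        p3 = st.freq(self.p3)[idx]
        p4 = st.pooled_freq(self.outgroups)[idx]
        usable = ~(np.isnan(p1) | np.isnan(p2) | np.isnan(p3) | np.isnan(p4))
        return p1, p2, p3, p4, usable


def site_terms(p1, p2, p3, p4):
    """Per-site (abba, baba, f_num, f_den) terms from frequency arrays.

    f_num is the per-site S term abba - baba; f_den is the dynamic-donor
    denominator term of f_dM (non-negative by construction).
    """
    p1 = np.asarray(p1, float); p2 = np.asarray(p2, float)
    p3 = np.asarray(p3, float); p4 = np.asarray(p4, float)
    abba = (1 - p1) * p2 * p3 * (1 - p4)
    baba = p1 * (1 - p2) * p3 * (1 - p4)
    f_num = abba - baba
    # p2 >= p1 branch: P_D = argmax(p2, p3), term S(P1; PD; PD; O)
    pd_hi = np.maximum(p2, p3)
    den_hi = (1 - p1) * pd_hi * pd_hi * (1 - p4) - p1 * (1 - pd_hi) * pd_hi * (1 - p4)
    # p2 < p1 branch: P_D = argmax(p1, p3), term -S(PD; P2; PD; O)
    pd_lo = np.maximum(p1, p3)
    den_lo = -((1 - pd_lo) * p2 * pd_lo * (1 - p4) - pd_lo * (1 - p2) * pd_lo * (1 - p4))
    f_den = np.where(p2 >= p1, den_hi, den_lo)
    return abba, baba, f_num, f_den


def d_statistic(st: SiteTable, quartet: QuartetSpec, sites=None):
    """(abba_sum, baba_sum, D) over the scoped sites; D is NaN when the
    denominator abba_sum + baba_sum vanishes."""
    p1, p2, p3, p4, ok = quartet.frequencies(st, sites)
    abba, baba, _, _ = site_terms(p1[ok], p2[ok], p3[ok], p4[ok])
    a, b = float(abba.sum()), float(baba.sum())
    d = (a - b) / (a + b) if (a + b) > 0 else float("nan")
    return a, b, d


def f_dm(st: SiteTable, quartet: QuartetSpec, sites=None) -> float:
    """f_dM over the scoped sites; NaN when the summed denominator is zero."""
    p1, p2, p3, p4, ok = quartet.frequencies(st, sites)
    _, _, num, den = site_terms(p1[ok], p2[ok], p3[ok], p4[ok])
    s_den = float(den.sum())
    return float(num.sum()) / s_den if s_den != 0 else float("nan")


# ---------------------------------------------------------------------------
# moving-block bootstrap
# ---------------------------------------------------------------------------

def moving_blocks(pos: np.ndarray, block_bp: int = 200) -> np.ndarray:
    """Half-open index ranges of the moving blocks of a sorted position array.

    One block starts at every site: block i covers sites with position in
    [pos[i], pos[i] + block_bp).  Returns an (n_blocks, 2) array of
    [start_index, end_index) pairs.
    """
    pos = np.asarray(pos)
    ends = np.searchsorted(pos, pos + block_bp, side="left")
    return np.column_stack([np.arange(pos.size), ends])


def _bootstrap_ratio_se(
    block_sums: np.ndarray,
    block_nsites: np.ndarray,
    n_sites: int,
    n_boot: int,
    rng: np.random.Generator,
    informative_sites: np.ndarray | None = None,
    span_bp: float | None = None,
    block_bp: int = 200,
) -> np.ndarray:
    """SEs of ratio statistics under block resampling.

    ``block_sums`` is (n_blocks, 2*n_stats): per-block numerator/denominator
    sums laid out as [num0, den0, num1, den1, ...].  A replicate draws block
    indices with replacement until the covered site count reaches n_sites.
    ``informative_sites`` gives, per statistic, the number of sites with a
    nonzero denominator term.  Returns an array of n_stats SEs (NaN where
    more than half the replicates leave the statistic undefined).

    The raw moving-block SE underestimates sampling variability on short
    spans: first-order deficits of (1 - b/L) from the span fraction one
    block removes and (1 - 1/k) from the k = ceil(L/b) non-overlapping
    blocks' degrees of freedom.  The returned SE is divided by
    sqrt((1 - b/L)(1 - 1/k)); spans no longer than one block give NaN (a
    single block's span cannot support an autocorrelation-robust variance).
    """
    n_blocks = block_sums.shape[0]
    n_stats = block_sums.shape[1] // 2
    if span_bp is not None and span_bp <= block_bp:
        return np.full(n_stats, np.nan)
    if n_blocks == 1:
        return np.full(n_stats, np.nan)
    if span_bp is not None:
        k_eff = np.ceil(span_bp / block_bp)
        correction = float(
            np.sqrt((1.0 - block_bp / span_bp) * (1.0 - 1.0 / k_eff))
        )
    else:
        correction = 1.0
    # a ratio statistic is invariant to how often a block is redrawn, so its
    # resampling variance is estimable only when the denominator mass comes
    # from at least two sites (which then occupy distinct moving blocks);
    # with a single informative site every defined replicate returns the
    # same ratio and the SE would be spuriously zero
    if informative_sites is None:
        informative_sites = np.full(n_stats, 2)
    mean_bs = max(block_nsites.mean(), 1.0)
    k = int(np.ceil(n_sites / mean_bs * 2)) + 4
    draws = rng.integers(0, n_blocks, size=(n_boot, k))
    covered = np.cumsum(block_nsites[draws], axis=1)
    # first column index at which coverage reaches n_sites; extend if needed
    while covered[:, -1].min() < n_sites:
        extra = rng.integers(0, n_blocks, size=(n_boot, k))
        draws = np.concatenate([draws, extra], axis=1)
        covered = np.cumsum(block_nsites[draws], axis=1)
        k *= 2
    need = np.argmax(covered >= n_sites, axis=1)
    use = np.arange(draws.shape[1])[None, :] <= need[:, None]
    sums = np.einsum("rk,rks->rs", use.astype(float), block_sums[draws])
    out = np.empty(n_stats)
    for s in range(n_stats):
        if informative_sites[s] < 2:
            out[s] = np.nan
            continue
        num, den = sums[:, 2 * s], sums[:, 2 * s + 1]
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = np.where(den != 0, num / den, np.nan)
        n_bad = np.isnan(vals).sum()
        if n_bad > n_boot / 2:
            out[s] = np.nan
        else:
            out[s] = np.nanstd(vals, ddof=1) / correction
    return out


def block_bootstrap_se(
    st: SiteTable,
    quartet: QuartetSpec,
    sites,
    stat: str = "D",
    block_bp: int = 200,
    n_boot: int = 1000,
    seed: int | None = None,
) -> float:
    """Moving-block bootstrap SE of D or f_dM for one unigene's sites."""
    if stat not in ("D", "f_dM"):
        raise ValueError("stat must be 'D' or 'f_dM'")
    idx = np.asarray(sites)
    p1, p2, p3, p4, ok = quartet.frequencies(st, idx)
    if ok.sum() == 0:
        raise ValueError("unigene has no usable site")
    pos = st.sites["pos"].to_numpy()[idx][ok]
    abba, baba, f_num, f_den = site_terms(p1[ok], p2[ok], p3[ok], p4[ok])
    if stat == "D":
        num, den = abba - baba, abba + baba
    else:
        num, den = f_num, f_den
    blocks = moving_blocks(pos, block_bp)
    csum_num = np.concatenate([[0.0], np.cumsum(num)])
    csum_den = np.concatenate([[0.0], np.cumsum(den)])
    bsums = np.column_stack([
        csum_num[blocks[:, 1]] - csum_num[blocks[:, 0]],
        csum_den[blocks[:, 1]] - csum_den[blocks[:, 0]],
    ])
    nsites = blocks[:, 1] - blocks[:, 0]
    rng = np.random.default_rng(seed)
    span = float(pos[-1] - pos[0] + 1) if pos.size > 1 else 1.0
    return float(
        _bootstrap_ratio_se(
            bsums, nsites, pos.size, n_boot, rng,
            informative_sites=np.array([(den != 0).sum()]),
            span_bp=span, block_bp=block_bp,
        )[0]
    )


# ---------------------------------------------------------------------------
# whole-transcriptome scan
# ---------------------------------------------------------------------------

@dataclass
class ScanResult:
    """Per-unigene scan table plus the transcriptome-wide d_XY context
    needed by the candidate screen."""

    table: pd.DataFrame
    dxy_transcriptome_mean: float
    block_dxy_all: np.ndarray
    block_dxy_gene: dict[str, np.ndarray]


def scan_unigenes(
    st: SiteTable,
    quartet: QuartetSpec,
    dxy_pair: tuple[str, str] | None = None,
    block_bp: int = 200,
    n_boot: int = 1000,
    seed: int | None = None,
) -> ScanResult:
    """Per-unigene D, f_dM, bootstrap SEs, Z-test P values, and d_XY.

    ``dxy_pair`` defaults to (donor, recipient) — the pair whose divergence
    separates introgression from incomplete lineage sorting.  Returns a
    :class:`ScanResult`: one table row per unigene, the transcriptome-wide
    mean per-site d_XY, and the pooled 200-bp-block d_XY distribution used
    by the screen.
    """
    if dxy_pair is None:
        dxy_pair = (quartet.p3, quartet.p2)
    uidx = unigene_index(st.sites)
    p1, p2, p3, p4, usable = quartet.frequencies(st)
    abba_s, baba_s, fnum_s, fden_s = site_terms(p1, p2, p3, p4)
    dxy_s = dxy_per_site(st, dxy_pair[0], dxy_pair[1])
    pos_all = st.sites["pos"].to_numpy()

    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(len(uidx))

    rows = []
    all_block_dxy: list[np.ndarray] = []
    gene_block_dxy: dict[str, np.ndarray] = {}
    for (gene, idx), child in zip(uidx.items(), child_seeds):
        ok = usable[idx] & ~np.isnan(dxy_s[idx])
        use = idx[ok]
        n_use = use.size
        if n_use == 0:
            rows.append(dict(unigene=gene, n_sites_used=0, abba_sum=np.nan,
                             baba_sum=np.nan, D=np.nan, f_dM=np.nan,
                             se_D=np.nan, se_f=np.nan, dxy_gene=np.nan))
            gene_block_dxy[gene] = np.empty(0)
            continue
        pos = pos_all[use]
        abba, baba = abba_s[use], baba_s[use]
        fnum, fden = fnum_s[use], fden_s[use]
        dxy_g = dxy_s[use]

        a, b = float(abba.sum()), float(baba.sum())
        d_val = (a - b) / (a + b) if (a + b) > 0 else np.nan
        fd = float(fden.sum())
        f_val = float(fnum.sum()) / fd if fd != 0 else np.nan

        blocks = moving_blocks(pos, block_bp)
        nsites = blocks[:, 1] - blocks[:, 0]

        def _bsum(x):
            c = np.concatenate([[0.0], np.cumsum(x)])
            return c[blocks[:, 1]] - c[blocks[:, 0]]

        bsums = np.column_stack([
            _bsum(abba - baba), _bsum(abba + baba), _bsum(fnum), _bsum(fden)
        ])
        rng = np.random.default_rng(child)
        span = float(pos[-1] - pos[0] + 1) if pos.size > 1 else 1.0
        se_d, se_f = _bootstrap_ratio_se(
            bsums, nsites, n_use, n_boot, rng,
            informative_sites=np.array(
                [((abba + baba) != 0).sum(), (fden != 0).sum()]
            ),
            span_bp=span, block_bp=block_bp,
        )

        blk_dxy = _bsum(dxy_g) / nsites
        gene_block_dxy[gene] = blk_dxy
        all_block_dxy.append(blk_dxy)

        rows.append(dict(unigene=gene, n_sites_used=n_use, abba_sum=a,
                         baba_sum=b, D=d_val, f_dM=f_val,
                         se_D=se_d, se_f=se_f,
                         dxy_gene=float(dxy_g.mean())))

    df = pd.DataFrame(rows)
    df["p_D"] = [z_test_two_tailed(v, s) for v, s in zip(df["D"], df["se_D"])]
    df["p_f"] = [z_test_two_tailed(v, s) for v, s in zip(df["f_dM"], df["se_f"])]

    dxy_all = dxy_s[usable & ~np.isnan(dxy_s)]
    return ScanResult(
        table=df,
        dxy_transcriptome_mean=(
            float(np.mean(dxy_all)) if dxy_all.size else float("nan")
        ),
        block_dxy_all=(
            np.concatenate(all_block_dxy) if all_block_dxy else np.empty(0)
        ),
        block_dxy_gene=gene_block_dxy,
    )


def screen_introgressed(
    scan: ScanResult,
    d_min: float = 0.7,
    alpha: float = 0.01,
    dxy_transcriptome_mean: float | None = None,
) -> pd.DataFrame:
    """Apply the candidate screen to a scan result (adds q values and flag).

    BH adjustment is applied within each statistic family across all tested
    unigenes.  The d_XY Mann-Whitney test is run only for genes whose mean
    d_XY is below the transcriptome mean; others are rejected outright.
    """
    df = scan.table.copy()
    if dxy_transcriptome_mean is None:
        dxy_transcriptome_mean = scan.dxy_transcriptome_mean
    if dxy_transcriptome_mean is None or np.isnan(dxy_transcriptome_mean):
        raise ValueError("transcriptome-wide mean d_XY is required")

    df["q_D"] = bh_fdr(df["p_D"].to_numpy())
    df["q_f"] = bh_fdr(df["p_f"].to_numpy())

    block_all = scan.block_dxy_all
    block_gene = scan.block_dxy_gene
    p_dxy = np.full(len(df), np.nan)
    low = df["dxy_gene"].to_numpy() < dxy_transcriptome_mean
    for i, gene in enumerate(df["unigene"]):
        if not low[i]:
            continue
        blk = block_gene.get(gene, np.empty(0))
        if blk.size == 0 or block_all.size == 0:
            continue
        p_dxy[i] = mann_whitney_u(blk, block_all)
    df["p_dxy"] = p_dxy
    df["q_dxy"] = bh_fdr(p_dxy)

    with np.errstate(invalid="ignore"):
        df["candidate"] = (
            (df["D"] >= d_min)
            & (df["q_D"] < alpha)
            & (df["q_f"] < alpha)
            & low
            & (df["q_dxy"] < alpha)
        ).fillna(False)
    df.attrs["dxy_transcriptome_mean"] = float(dxy_transcriptome_mean)
    return df
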