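"""Positive-selection scan: population branch statistic and HKA-style test.

For a target population T, control C and outgroup O, per-unigene pairwise
Weir-Cockerham F_ST values are converted to branch-scaled divergence times
T = -log(1 - F_ST), and the target's branch length is

    PBS_T = (T_TC + T_TO - T_CO) / 2.

F_ST is clamped to [0, 1 - 1e-6] before the log: negative per-gene estimates
(sampling noise) would otherwise produce negative times, and F_ST = 1 an
infinite one.

The HKA-style test contrasts, per unigene, the number of sites polymorphic
within the target (A) against the number of fixed differences where the
target is fixed for one allele while both the control population and the HKA
outgroup are fixed for the other (B), via a Pearson chi-square of
[[A_gene, B_gene], [A_rest, B_rest]] against the transcriptome-wide totals.

A gene is called positively selected when its PBS reaches the top decile of
defined PBS values and its HKA P value is below 0.05 (raw, no FDR).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import SiteTable, unigene_index
from .popgen import fst_wc_components
from .stats import chi2_2x2

__all__ = [
    "pbs_from_fst",
    "hka_site_classes",
    "selection_scan",
    "call_psgs",
]

FST_CAP = 1.0 - 1e-6


def pbs_from_fst(fst_tc: float, fst_to: float, fst_co: float) -> float:
    """PBS of the target from the three pairwise F_ST values; NaN if any is
    undefined."""
    vals = np.array([fst_tc, fst_to, fst_co], dtype=float)
    if np.any(np.isnan(vals)):
        return float("nan")
    t = -np.log(1.0 - np.clip(vals, 0.0, FST_CAP))
    return float((t[0] + t[1] - t[2]) / 2.0)


def _fixed_state(k: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Per-site fixed-allele code: 0 ancestral-fixed, 1 derived-fixed,
    -9 polymorphic or uncalled."""
    state = np.full(k.shape, -9, dtype=np.int8)
    state[(n > 0) & (k == 0)] = 0
    state[(n > 0) & (k == n)] = 1
    return state


def hka_site_classes(
    st: SiteTable, target: str, control: str, hka_outgroup: str
) -> tuple[np.ndarray, np.ndarray]:
    """Boolean per-site arrays (is_A, is_B).

    A: segregating within the target.  B: target fixed for one allele while
    control AND outgroup are both fixed for the other.  A site polymorphic in
    the target can count toward A but never B.
    """
    kt, nt = st.counts(target)
    kc, nc = st.counts(control)
    ko, no = st.counts(hka_outgroup)
    is_a = (nt > 0) & (kt > 0) & (kt < nt)
    t_state = _fixed_state(kt, nt)
    c_state = _fixed_state(kc, nc)
    o_state = _fixed_state(ko, no)
    is_b = (
        (t_state >= 0)
        & (c_state >= 0)
        & (o_state >= 0)
        & (c_state == o_state)
        & (t_state != c_state)
    )
    return is_a, is_b


def selection_scan(
    st: SiteTable,
    target: str,
    control: str,
    pbs_outgroup: str,
    hka_outgroup: str,
) -> pd.DataFrame:
    """Per-unigene PBS and HKA records for one target population.

    Returns one row per unigene with the three pairwise F_ST values, branch
    times, PBS, HKA counts A/B, and the chi-square P against the
    transcriptome-wide A/B ratio (NaN and excluded from PSG calling when a
    margin of the 2x2 table is zero).
    """
    uidx = unigene_index(st.sites)
    kt, nt = st.counts(target)
    kc, nc = st.counts(control)
    ko, no = st.counts(pbs_outgroup)

    num_tc, den_tc = fst_wc_components(kt, nt, kc, nc)
    num_to, den_to = fst_wc_components(kt, nt, ko, no)
    num_co, den_co = fst_wc_components(kc, nc, ko, no)
    is_a, is_b = hka_site_classes(st, target, control, hka_outgroup)

    rows = []
    for gene, idx in uidx.items():
        def _fst(num, den):
            n, d = np.nansum(num[idx]), np.nansum(den[idx])
            return float(n / d) if d != 0 and not np.all(np.isnan(num[idx])) else float("nan")

        f_tc, f_to, f_co = _fst(num_tc, den_tc), _fst(num_to, den_to), _fst(num_co, den_co)
        rows.append(dict(
            unigene=gene,
            fst_TC=f_tc, fst_TO=f_to, fst_CO=f_co,
            pbs=pbs_from_fst(f_tc, f_to, f_co),
            hka_A=int(is_a[idx].sum()),
            hka_B=int(is_b[idx].sum()),
        ))
    df = pd.DataFrame(rows)
    for col, f in (("T_TC", "fst_TC"), ("T_TO", "fst_TO"), ("T_CO", "fst_CO")):
        df[col] = -np.log(1.0 - np.clip(df[f].to_numpy(dtype=float), 0.0, FST_CAP))

    a_tot = int(df["hka_A"].sum())
    b_tot = int(df["hka_B"].sum())
    chi2_p = np.full(len(df), np.nan)
    for i, (a, b) in enumerate(zip(df["hka_A"], df["hka_B"])):
        table = [[a, b], [a_tot - a, b_tot - b]]
        chi2_p[i] = chi2_2x2(table)
    df["chi2_p"] = chi2_p
    df["target"] = target
    df.attrs["hka_A_total"] = a_tot
    df.attrs["hka_B_total"] = b_tot
    return df


def call_psgs(
    records: pd.DataFrame,
    pbs_quantile: float = 0.90,
    hka_alpha: float = 0.05,
) -> pd.DataFrame:
    """Flag positively selected genes: PBS at or above the empirical
    ``pbs_quantile`` of defined PBS values and HKA chi-square P < hka_alpha.

    Genes with undefined PBS or HKA P are never flagged; the percentile is
    taken over all genes with defined PBS.
    """
    df = records.copy()
    pbs_vals = df["pbs"].to_numpy(dtype=float)
    defined = ~np.isnan(pbs_vals)
    if defined.sum() < 10:
        raise ValueError("need at least 10 unigenes with defined PBS")
    cutoff = float(np.quantile(pbs_vals[defined], pbs_quantile))
    with np.errstate(invalid="ignore"):
        df["psg"] = (pbs_vals >= cutoff) & (df["chi2_p"].to_numpy() < hka_alpha)
    df.attrs = dict(records.attrs)
    df.attrs["pbs_cutoff"] = cutoff
    return df
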