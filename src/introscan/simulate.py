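"""Truth-labelled synthetic genotype data for exercising the scans.

The generator emulates the statistical structure the analysis assumes: a
rooted population tree (((recipient-north, control-south), donor), outgroups)
with per-branch drift, unigene-structured SNPs, donor-to-recipient admixture
planted at whole unigenes, and target-branch selective shifts planted at
others.

Each SNP is assigned a mutation-origin class: the derived allele either
segregated in the root ancestor (shared, ancestral polymorphism — the
incomplete-lineage-sorting source), arose on the internal branch leading to
the two recipient-side populations, arose privately on one terminal branch,
or represents a sorted near-fixed difference on either side of the
donor/recipient-lineage split.  Populations outside the originating subtree
have derived frequency zero; populations inside it drift from the origin
frequency under the
Balding-Nichols model: a child's frequency is Beta(p (1-F)/F, (1-p) (1-F)/F)
around its parent's p, with F the per-branch drift parameter.  This mirrors
real SNP data, where most variants are lineage-specific and only a fraction
trace to shared ancestral polymorphism; a scan could not distinguish
introgression from drift at all if every site were ancestrally shared.

Polarization outgroups are held fixed for the ancestral allele, so the
planted ABBA/BABA polarity is exact and truth labels are unambiguous.
Introgression is modelled as frequency admixture applied after drift at
whole unigenes (the scan unit): p_recipient <- (1-alpha) p_recipient +
alpha p_donor; it thereby carries donor-private alleles into the recipient,
the signature the D and f_dM statistics respond to.  Selection pushes the
target branch's frequency toward the nearer boundary by ``selection_shift``.

This is a drift-equilibrium generator, not a coalescent: it reproduces the
frequency covariance structure the statistics respond to with closed-form
expectations, but no linkage, recombination, or mutation-age structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io import (
    GenotypeMatrix,
    PopulationMap,
    MISSING,
    ROLE_CONTROL,
    ROLE_DONOR,
    ROLE_OUTGROUP_POLARIZE,
    ROLE_OUTGROUP_SELECTION,
    ROLE_RECIPIENT,
    write_vcf,
)

__all__ = ["SimConfig", "SimTruth", "simulate_frequencies",
           "sample_genotypes", "simulate_dataset", "write_dataset",
           "default_popmap"]

LABEL_NEUTRAL = "neutral"
LABEL_INTROGRESSED = "introgressed"
LABEL_SELECTED_TARGET = "selected_target"
LABEL_SELECTED_RECIPIENT = "selected_recipient"


@dataclass
class SimConfig:
    """Generator parameters.

    Defaults mirror the study regime: 65 diploid ingroup individuals
    (35 donor / 10 recipient-north / 20 control-south), single-individual
    polarization outgroups, a nine-individual selection outgroup, unigenes
    of 200-2000 bp carrying 30-90 planted SNPs each (roughly 30 survive
    sampling and filtering, matching the complete-call transcriptome's ~30
    SNPs per unigene), and 10% of unigenes introgressed at admixture
    fraction 0.9.  The origin-class weights are calibrated so every screen
    component (D magnitude, both Z-tests, the d_XY contrast) carries signal
    at planted loci while neutral loci stay null: lineage-specific
    polymorphism dominates, sorted substitutions supply the divergence
    background the d_XY filter needs, and a small shared-ancestral class
    provides the incomplete-lineage-sorting noise floor.
    """

    n_unigenes: int = 500
    unigene_len_bp: tuple[int, int] = (200, 2000)
    snps_per_unigene: tuple[int, int] = (30, 90)
    sample_sizes: dict[str, int] = field(default_factory=lambda: {
        "Cgi": 35, "CduN": 10, "CduS": 20, "Cfu": 1, "Jmi": 1, "Cch": 9,
    })
    drift: dict[str, float] = field(default_factory=lambda: {
        "Cgi": 0.25, "CduAnc": 0.10, "CduN": 0.08, "CduS": 0.08, "Cch": 0.40,
    })
    # mutation-origin class weights: shared root polymorphism, variants of
    # the recipient-side (Cdu) lineage, one private class per sampled
    # population, and near-fixed sorted differences on either side of the
    # donor/recipient-lineage split (the divergence that introgression
    # locally erases and that the d_XY filter keys on)
    origin_weights: dict[str, float] = field(default_factory=lambda: {
        "ancestral": 0.05, "CduAnc": 0.12,
        "Cgi": 0.22, "CduN": 0.05, "CduS": 0.08, "Cch": 0.14,
        "Cgi_sub": 0.24, "Cdu_sub": 0.10,
    })
    ancestral_freq_beta: tuple[float, float] = (0.25, 2.5)
    private_freq_beta: tuple[float, float] = (0.35, 1.0)
    substitution_freq_beta: tuple[float, float] = (12.0, 2.0)
    introgressed_fraction: float = 0.10
    admixture_alpha: float = 0.9
    selected_fraction: float = 0.04
    selected_recipient_fraction: float = 0.02
    selection_shift: float = 0.6
    missing_rate: float = 0.02
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("introgressed_fraction", "admixture_alpha",
                     "selected_fraction", "selected_recipient_fraction",
                     "selection_shift", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for branch, f in self.drift.items():
            if not 0.0 < f < 1.0:
                raise ValueError(f"drift F for {branch} must lie in (0, 1)")


@dataclass
class SimTruth:
    """Ground truth: per-unigene labels and realized population frequencies."""

    labels: dict[str, str]
    unigene_len: dict[str, int]
    freqs: pd.DataFrame  # unigene, pos, and one frequency column per population

    def unigenes_with(self, label: str) -> list[str]:
        return [u for u, lab in self.labels.items() if lab == label]


def _balding_nichols(rng: np.random.Generator, p: np.ndarray, f: float) -> np.ndarray:
    """Child frequencies after drift F around parent frequencies p."""
    if f <= 1e-9:
        return p.copy()
    scale = (1.0 - f) / f
    out = np.empty_like(p)
    interior = (p > 0) & (p < 1)
    out[~interior] = p[~interior]  # fixed states stay fixed under pure drift
    pi = p[interior]
    out[interior] = rng.beta(pi * scale, (1.0 - pi) * scale)
    return out


def simulate_frequencies(cfg: SimConfig, rng: np.random.Generator | None = None):
    """Draw per-site population frequencies along the tree plus truth labels.

    Returns (freqs: DataFrame with unigene/pos and a column per ingroup +
    selection-outgroup population, truth: SimTruth).  Polarization outgroups
    are fixed ancestral (derived frequency 0) and carry no columns.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)

    n_intro = round(cfg.n_unigenes * cfg.introgressed_fraction)
    n_sel_t = round(cfg.n_unigenes * cfg.selected_fraction)
    n_sel_r = round(cfg.n_unigenes * cfg.selected_recipient_fraction)
    if n_intro + n_sel_t + n_sel_r > cfg.n_unigenes:
        raise ValueError("planted fractions exceed the number of unigenes")
    labels_arr = np.array(
        [LABEL_INTROGRESSED] * n_intro
        + [LABEL_SELECTED_TARGET] * n_sel_t
        + [LABEL_SELECTED_RECIPIENT] * n_sel_r
        + [LABEL_NEUTRAL] * (cfg.n_unigenes - n_intro - n_sel_t - n_sel_r)
    )
    rng.shuffle(labels_arr)

    width = len(str(cfg.n_unigenes))
    names = [f"UG{str(i + 1).zfill(width)}" for i in range(cfg.n_unigenes)]
    labels = dict(zip(names, labels_arr))

    lens = rng.integers(cfg.unigene_len_bp[0], cfg.unigene_len_bp[1] + 1,
                        size=cfg.n_unigenes)
    a, b = cfg.ancestral_freq_beta
    ap, bp = cfg.private_freq_beta
    classes = list(cfg.origin_weights)
    weights = np.array([cfg.origin_weights[c] for c in classes], dtype=float)
    weights = weights / weights.sum()

    recs = []
    for name, lab, length in zip(names, labels_arr, lens):
        lo, hi = cfg.snps_per_unigene
        n_snp = int(rng.integers(lo, hi + 1))
        n_snp = min(n_snp, int(length))
        pos = np.sort(rng.choice(np.arange(1, length + 1), size=n_snp,
                                 replace=False))
        origin = rng.choice(len(classes), p=weights, size=n_snp)
        freqs = {g: np.zeros(n_snp) for g in ("Cgi", "CduN", "CduS", "Cch")}

        def _cls(name: str) -> np.ndarray:
            if name not in classes:
                return np.zeros(n_snp, dtype=bool)
            return origin == classes.index(name)

        anc = _cls("ancestral")
        if anc.any():
            p0 = rng.beta(a, b, size=int(anc.sum()))
            p_cdu_anc = _balding_nichols(rng, p0, cfg.drift["CduAnc"])
            freqs["Cgi"][anc] = _balding_nichols(rng, p0, cfg.drift["Cgi"])
            freqs["CduN"][anc] = _balding_nichols(rng, p_cdu_anc, cfg.drift["CduN"])
            freqs["CduS"][anc] = _balding_nichols(rng, p_cdu_anc, cfg.drift["CduS"])
            freqs["Cch"][anc] = _balding_nichols(rng, p0, cfg.drift["Cch"])
        internal = _cls("CduAnc")
        if internal.any():
            p_int = rng.beta(ap, bp, size=int(internal.sum()))
            freqs["CduN"][internal] = _balding_nichols(rng, p_int, cfg.drift["CduN"])
            freqs["CduS"][internal] = _balding_nichols(rng, p_int, cfg.drift["CduS"])
        for pop in ("Cgi", "CduN", "CduS", "Cch"):
            private = _cls(pop)
            if private.any():
                freqs[pop][private] = rng.beta(ap, bp, size=int(private.sum()))
        asub, bsub = cfg.substitution_freq_beta
        gsub = _cls("Cgi_sub")
        if gsub.any():
            freqs["Cgi"][gsub] = rng.beta(asub, bsub, size=int(gsub.sum()))
        dsub = _cls("Cdu_sub")
        if dsub.any():
            p_int = rng.beta(asub, bsub, size=int(dsub.sum()))
            freqs["CduN"][dsub] = _balding_nichols(rng, p_int, cfg.drift["CduN"])
            freqs["CduS"][dsub] = _balding_nichols(rng, p_int, cfg.drift["CduS"])

        if lab == LABEL_INTROGRESSED:
            freqs["CduN"] = (
                (1 - cfg.admixture_alpha) * freqs["CduN"]
                + cfg.admixture_alpha * freqs["Cgi"]
            )
        elif lab == LABEL_SELECTED_TARGET:
            freqs["Cgi"] = _shift_to_boundary(freqs["Cgi"], cfg.selection_shift)
        elif lab == LABEL_SELECTED_RECIPIENT:
            freqs["CduN"] = _shift_to_boundary(freqs["CduN"], cfg.selection_shift)
        rec = pd.DataFrame({"unigene": name, "pos": pos, **freqs})
        recs.append(rec)
    freqs_df = pd.concat(recs, ignore_index=True)
    truth = SimTruth(labels=labels,
                     unigene_len=dict(zip(names, (int(x) for x in lens))),
                     freqs=freqs_df)
    return freqs_df, truth


def _shift_to_boundary(p: np.ndarray, shift: float) -> np.ndarray:
    """Push each frequency toward its nearer boundary by fraction ``shift``."""
    target = (p >= 0.5).astype(float)
    return p + shift * (target - p)


def default_popmap(cfg: SimConfig) -> PopulationMap:
    """Population map matching the generator's group layout and roles."""
    assignments: dict[str, str] = {}
    for group, n in cfg.sample_sizes.items():
        for i in range(n):
            assignments[f"{group}_{i + 1:02d}"] = group
    return PopulationMap(
        assignments=assignments,
        roles={
            ROLE_DONOR: "Cgi",
            ROLE_RECIPIENT: "CduN",
            ROLE_CONTROL: "CduS",
            ROLE_OUTGROUP_POLARIZE: ["Cfu", "Jmi"],
            ROLE_OUTGROUP_SELECTION: "Cch",
        },
    )


def sample_genotypes(
    freqs: pd.DataFrame,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[GenotypeMatrix, PopulationMap]:
    """Draw diploid genotypes from population frequencies.

    Dosages are Binomial(2, p) per individual; polarization outgroups are
    homozygous ancestral.  Ref/alt labels are randomized per site (derived is
    alt at ~half the sites) so polarization is genuinely exercised.
    Missingness is i.i.d.; sites monomorphic across all samples after
    sampling are dropped, mimicking SNP-calling output.
    """
    if rng is None:
        rng = np.random.default_rng(None if cfg.seed is None else cfg.seed + 1)
    popmap = default_popmap(cfg)
    samples = list(popmap.assignments)
    n_sites = len(freqs)

    calls = np.zeros((len(samples), n_sites), dtype=np.int8)
    row = 0
    for group, n in cfg.sample_sizes.items():
        if group in freqs.columns:
            p = freqs[group].to_numpy()
            calls[row:row + n] = rng.binomial(2, p, size=(n, n_sites)).astype(np.int8)
        # polarization outgroups: fixed ancestral -> dosage stays 0
        row += n

    if cfg.missing_rate > 0:
        miss = rng.random(calls.shape) < cfg.missing_rate
        calls[miss] = MISSING

    # random ref/alt labelling: where flipped, the derived allele is REF
    flip = rng.random(n_sites) < 0.5
    obs = calls != MISSING
    calls[:, flip] = np.where(obs[:, flip], 2 - calls[:, flip], MISSING)

    bases = np.array(list("ACGT"))
    anc = bases[rng.integers(0, 4, size=n_sites)]
    der = bases[(np.char.find("ACGT", anc) + rng.integers(1, 4, size=n_sites)) % 4]
    ref = np.where(flip, der, anc)
    alt = np.where(flip, anc, der)

    poly = np.zeros(n_sites, dtype=bool)
    any_ref = (obs & (calls < 2)).any(axis=0)
    any_alt = (obs & (calls > 0)).any(axis=0)
    poly = any_ref & any_alt

    sites = pd.DataFrame({
        "unigene": freqs["unigene"].to_numpy(),
        "pos": freqs["pos"].to_numpy(),
        "ref": ref,
        "alt": alt,
    })
    gm = GenotypeMatrix(samples=samples, sites=sites, calls=calls)
    gm = gm.take_sites(np.nonzero(poly)[0])
    return gm, popmap


def simulate_dataset(cfg: SimConfig):
    """Full in-memory dataset: (GenotypeMatrix, PopulationMap, SimTruth)."""
    rng = np.random.default_rng(cfg.seed)
    freqs, truth = simulate_frequencies(cfg, rng)
    gm, popmap = sample_genotypes(freqs, cfg, rng)
    gm.unigene_lengths = dict(truth.unigene_len)
    return gm, popmap, truth


def write_dataset(cfg: SimConfig, out_prefix) -> dict[str, Path]:
    """Simulate and write VCF + popmap + truth + resolved-config files."""
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    gm, popmap, truth = simulate_dataset(cfg)

    paths = {
        "vcf": out_prefix.with_suffix(".vcf"),
        "popmap": out_prefix.parent / (out_prefix.name + ".popmap.tsv"),
        "truth": out_prefix.parent / (out_prefix.name + ".truth.tsv"),
        "config": out_prefix.parent / (out_prefix.name + ".config-resolved.yaml"),
    }
    write_vcf(gm, paths["vcf"])
    with open(paths["popmap"], "w") as fh:
        for s, g in popmap.assignments.items():
            fh.write(f"{s}\t{g}\n")
    truth_df = pd.DataFrame(
        {
            "unigene": list(truth.labels),
            "label": list(truth.labels.values()),
            "length_bp": [truth.unigene_len[u] for u in truth.labels],
        }
    )
    truth_df.to_csv(paths["truth"], sep="\t", index=False)
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=False)
    return paths
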