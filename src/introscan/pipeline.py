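"""End-to-end orchestration: filters -> polarize -> diversity -> scans ->
overlap test, from a single config, with per-stage manifests.

Stages run in a fixed order and each writes a TSV (with a leading ``# key=value``
metadata block) plus an entry in ``manifest.json`` recording inputs, seeds and
site counts in/out, so conservation can be audited per filter.  One global
seed fans out to per-stage seeds through ``numpy.random.SeedSequence`` spawn
keys, making every stage individually reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as iom
from .introgression import QuartetSpec, scan_unigenes, screen_introgressed
from .popgen import dxy, fst_wc, theta_pi
from .selection import call_psgs, selection_scan
from .sharing import overlap_null, rare_sharing

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_full"]


@dataclass
class RunConfig:
    """Inputs, group roles and thresholds for a full run."""

    vcf: str
    popmap: str
    out_dir: str
    roles: dict[str, object] = field(default_factory=lambda: {
        "donor": "Cgi", "recipient": "CduN", "control": "CduS",
        "outgroup_polarize": ["Cfu", "Jmi"], "outgroup_selection": "Cch",
    })
    hka_outgroup: str | None = None  # defaults to first polarization outgroup
    exclude_samples: list[str] = field(default_factory=list)
    min_presence: float = 0.6
    d_min: float = 0.7
    alpha: float = 0.01
    pbs_quantile: float = 0.90
    hka_alpha: float = 0.05
    block_bp: int = 200
    n_boot: int = 1000
    k_range: tuple[int, int] = (2, 5)
    overlap_reps: int = 100_000
    seed: int = 0
    resume: bool = False

    def __post_init__(self) -> None:
        checks = [
            ("min_presence", 0.0, 1.0), ("d_min", -1.0, 1.0),
            ("alpha", 0.0, 1.0), ("pbs_quantile", 0.0, 1.0),
            ("hka_alpha", 0.0, 1.0),
        ]
        for name, lo, hi in checks:
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        if self.block_bp <= 0 or self.n_boot <= 0 or self.overlap_reps <= 0:
            raise ValueError("block_bp, n_boot and overlap_reps must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "k_range" in raw:
            raw["k_range"] = tuple(raw["k_range"])
        return cls(**raw)


def _write_tsv(df: pd.DataFrame, path: Path, meta: dict) -> None:
    with open(path, "w") as fh:
        for k, v in meta.items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, sep="\t", index=False)


def _hash_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def run_full(cfg: RunConfig) -> dict:
    """Execute the full analysis; returns the manifest dictionary."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    config_ser = {k: (list(v) if isinstance(v, tuple) else v)
                  for k, v in asdict(cfg).items()}
    inputs = {"vcf": _hash_file(cfg.vcf), "popmap": _hash_file(cfg.popmap)}
    if cfg.resume and manifest_path.exists():
        prev = json.loads(manifest_path.read_text())
        prev_cfg = {k: v for k, v in prev.get("config", {}).items() if k != "resume"}
        cur_cfg = {k: v for k, v in config_ser.items() if k != "resume"}
        if prev_cfg == cur_cfg and prev.get("inputs") == inputs:
            logger.info("resume: completed run found, outputs reused")
            return prev
    manifest: dict = {"config": config_ser, "inputs": inputs, "stages": {}}
    ss = np.random.SeedSequence(cfg.seed)
    stage_seeds = {name: int(s.generate_state(1)[0] % (2 ** 31))
                   for name, s in zip(
                       ["scan", "selection", "overlap"], ss.spawn(3))}

    popmap = iom.PopulationMap(
        assignments=iom.read_popmap(cfg.popmap), roles=dict(cfg.roles)
    )

    # --- load + filter -----------------------------------------------------
    gm = iom.read_vcf(cfg.vcf, popmap)
    n0 = gm.n_sites
    gm = iom.filter_missingness(gm, cfg.min_presence)
    manifest["stages"]["filter_missingness"] = {
        "sites_in": n0, "sites_kept": gm.n_sites,
        "sites_dropped": n0 - gm.n_sites,
    }

    # --- polarize ----------------------------------------------------------
    st = iom.polarize(gm, popmap)
    manifest["stages"]["polarize"] = {
        "sites_in": gm.n_sites, "sites_kept": st.n_sites,
        "sites_dropped": gm.n_sites - st.n_sites,
    }

    donor = popmap.roles["donor"]
    recipient = popmap.roles["recipient"]
    control = popmap.roles["control"]
    sel_out = popmap.roles.get("outgroup_selection")
    hka_out = cfg.hka_outgroup or popmap.polarize_outgroups()[0]

    # --- diversity / divergence -------------------------------------------
    div_rows = []
    for grp in (donor, recipient, control):
        rec = theta_pi(st, grp)
        div_rows.append(dict(group=grp, scope=rec.scope, L=rec.L, S=rec.S,
                             theta_pi=rec.theta_pi, theta_w=rec.theta_w))
    div_df = pd.DataFrame(div_rows)
    pair_rows = []
    for a, b in ((donor, recipient), (donor, control), (recipient, control)):
        rec = fst_wc(st, a, b)
        pair_rows.append(dict(group_a=a, group_b=b, fst=rec.fst, dxy=rec.dxy))
    pair_df = pd.DataFrame(pair_rows)
    _write_tsv(div_df, out / "diversity.tsv", {"stage": "diversity"})
    _write_tsv(pair_df, out / "divergence.tsv", {"stage": "divergence"})
    manifest["stages"]["diversity"] = {"groups": [donor, recipient, control]}

    # --- introgression scan ------------------------------------------------
    quartet = QuartetSpec(p1=control, p2=recipient, p3=donor,
                          outgroups=popmap.polarize_outgroups())
    scan = scan_unigenes(st, quartet, block_bp=cfg.block_bp,
                         n_boot=cfg.n_boot, seed=stage_seeds["scan"])
    screened = screen_introgressed(scan, d_min=cfg.d_min, alpha=cfg.alpha)
    _write_tsv(
        screened.drop(columns=[], errors="ignore"),
        out / "introgression_scan.tsv",
        {
            "stage": "introgression_scan",
            "seed": stage_seeds["scan"],
            "dxy_transcriptome_mean": screened.attrs["dxy_transcriptome_mean"],
        },
    )
    intro_set = screened.loc[screened["candidate"], "unigene"].tolist()
    (out / "introgressed_candidates.txt").write_text(
        "\n".join(intro_set) + ("\n" if intro_set else "")
    )
    manifest["stages"]["introgression_scan"] = {
        "unigenes_tested": int(len(screened)),
        "candidates": len(intro_set),
        "seed": stage_seeds["scan"],
    }

    # --- selection scans (donor and recipient targets) ---------------------
    st_sel = st
    if cfg.exclude_samples:
        popmap_sel = popmap.exclude(cfg.exclude_samples)
        st_sel = iom.polarize(gm, popmap_sel)
    psg_sets = {}
    for tag, target in (("donor", donor), ("recipient", recipient)):
        sel = selection_scan(st_sel, target=target, control=control,
                             pbs_outgroup=sel_out, hka_outgroup=hka_out)
        sel = call_psgs(sel, pbs_quantile=cfg.pbs_quantile,
                        hka_alpha=cfg.hka_alpha)
        _write_tsv(sel, out / f"selection_{tag}.tsv",
                   {"stage": f"selection_{tag}",
                    "pbs_cutoff": sel.attrs["pbs_cutoff"]})
        ids = sel.loc[sel["psg"], "unigene"].tolist()
        psg_sets[tag] = ids
        (out / f"psg_{tag}.txt").write_text("\n".join(ids) + ("\n" if ids else ""))
        manifest["stages"][f"selection_{tag}"] = {
            "unigenes": int(len(sel)), "psgs": len(ids),
        }

    # --- rare-allele sharing ------------------------------------------------
    sharing = rare_sharing(st, (donor, recipient, control), cfg.k_range)
    _write_tsv(sharing, out / "rare_sharing.tsv", {"stage": "rare_sharing"})
    manifest["stages"]["rare_sharing"] = {
        "complete_sites": sharing.attrs["n_complete_sites"],
    }

    # --- overlap null -------------------------------------------------------
    pool = int(len(screened))
    observed = len(
        set(intro_set) & set(psg_sets["donor"]) & set(psg_sets["recipient"])
    )
    null = overlap_null(
        pool_size=max(pool, 1),
        set_sizes=(len(intro_set), len(psg_sets["donor"]),
                   len(psg_sets["recipient"])),
        n_reps=cfg.overlap_reps,
        seed=stage_seeds["overlap"],
    )
    overlap_summary = {
        "pool_size": null.pool_size,
        "set_sizes": list(null.set_sizes),
        "n_reps": null.n_reps,
        "seed": stage_seeds["overlap"],
        "observed_overlap": observed,
        "max_overlap": null.max_overlap,
        "mean_overlap": null.mean_overlap,
        "p_ge_observed": null.p_ge(observed),
    }
    (out / "overlap_null.json").write_text(
        json.dumps(overlap_summary, indent=2) + "\n"
    )
    manifest["stages"]["overlap_null"] = overlap_summary

    manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
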