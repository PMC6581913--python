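# introscan

Per-unigene scans for **adaptive introgression** in a three-population
species complex, built for transcriptome-derived SNP data where the locus
unit is an assembled unigene rather than a chromosome window.

The motivating system is a pair of cypress species on the Qinghai-Tibet
Plateau: a high-elevation donor species (*Cupressus gigantea*, "Cgi"), a
recipient lineage of northern *C. duclouxiana* populations ("CduN") whose
range extends into similar cool, dry mountain habitat, and the southern
*C. duclouxiana* populations ("CduS") that act as the non-introgressed
control, with *C. funebris* and *Juniperus microsperma* as polarization
outgroups and *C. chengiana* ("Cch") as the outgroup for selection scans.
The same machinery applies to any four-taxon layout
((control, recipient), donor) + outgroups.

## What it computes

**Introgression scan.** For each unigene, with derived-allele frequencies
p̂₁..p̂₄ in (P1 = control, P2 = recipient, P3 = donor, O = pooled outgroups):

- Patterson's D:
  `D = Σ[(1−p̂₁)p̂₂p̂₃(1−p̂₄) − p̂₁(1−p̂₂)p̂₃(1−p̂₄)] / Σ[(1−p̂₁)p̂₂p̂₃(1−p̂₄) + p̂₁(1−p̂₂)p̂₃(1−p̂₄)]`
- the dynamic-denominator admixture-fraction estimator f_dM, which
  substitutes the locally most-derived population P_D into the donor slots
  and is bounded in [−1, 1];
- moving-block bootstrap standard errors (200-bp blocks along the unigene),
  two-tailed Z-tests of D and f_dM against zero, and Benjamini-Hochberg
  adjustment across unigenes;
- donor-recipient d_XY per gene, compared against the transcriptome-wide
  distribution of 200-bp-block d_XY by a Mann-Whitney U test — the filter
  that separates introgression (locally *reduced* divergence) from
  incomplete lineage sorting.

A unigene is called introgressed when D ≥ 0.7, q_D < 0.01, q_f < 0.01, its
mean d_XY lies below the transcriptome mean, and q_dxy < 0.01.

**Selection scan.** Per unigene, pairwise Weir-Cockerham F_ST among target,
control and outgroup populations are converted to branch-scaled times
T = −log(1 − F_ST) and combined into the population branch statistic
`PBS = (T_TC + T_TO − T_CO) / 2`; an HKA-style test contrasts target
polymorphism (A) against fixed differences (B) relative to the
transcriptome-wide A/B ratio with a Pearson chi-square. Positively selected
genes (PSGs) are the top 10% of PBS with HKA P < 0.05.

**Gene-flow corroboration.** Rare-SNP sharing (derived-allele count 2-5 of
the 130 pooled ingroup alleles) tallied as pairwise-exclusive sharing
proportions per frequency category, and an overlap resampling null that
asks how many genes three independently drawn candidate sets would share
by chance.

**Synthetic data.** A truth-labelled generator plants introgressed and
selected unigenes in a drift-simulated three-population transcriptome
(Balding-Nichols drift over mutation-origin classes), so every stage of the
chain is verifiable against known labels — see `docs/methods.md`.

## Worked example

```sh
introscan simulate --seed 4 --out-prefix demo/sim
introscan dstat --vcf demo/sim.vcf --popmap demo/sim.popmap.tsv \
    --quartet P1=CduS,P2=CduN,P3=Cgi,O=Cfu+Jmi \
    --block 200 --boot 1000 --seed 2 --out demo/scan.tsv
```

prints

```
unigenes=500 candidates=44
```

i.e. 44 of the 500 simulated unigenes pass the full screen; the truth file
`demo/sim.truth.tsv` labels 50 as introgressed, and all 44 calls are among
them (`demo/scan.tsv` has one row per unigene with D, f_dM, their
bootstrap SEs, raw and BH-adjusted P values, per-gene d_XY and the
candidate flag). The selection scan and the chance-overlap test follow the
same pattern:

```sh
introscan pbs-hka --vcf demo/sim.vcf --popmap demo/sim.popmap.tsv \
    --target Cgi --control CduS --pbs-outgroup Cch --hka-outgroup Cfu \
    --out demo/psg.tsv
introscan overlap-null --pool 16884 --sizes 1285,730,248 \
    --reps 100000 --seed 1 --observed 16
```

The selection scan reports `unigenes=500 psgs=13`, and the last command
prints a JSON summary in which `max_overlap` is 7 and `p_ge_observed` is
0.0: sixteen shared genes among three such sets is far beyond what
independent draws produce.

`introscan run --config run.yaml` executes the whole chain (filters →
polarization → diversity statistics → introgression scan → two selection
scans → rare sharing → overlap test) with per-stage TSV outputs and a
`manifest.json` recording seeds and site counts in/out of every filter.
`introscan sfs-export` writes site-frequency spectra either as plain-text
"dadi-style" (line 1: shape integers plus `folded`/`unfolded`; line 2:
flattened C-order counts; line 3: a 0/1 mask, all zeros) or as a
fastsimcoal-style `.obs` (line 1: `1 observations.` header; line 2: number
of demes and per-deme haploid sizes; line 3: flattened C-order counts).

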