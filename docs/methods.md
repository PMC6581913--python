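# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the known limitations of `introscan`. Nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Data model

All statistics operate on a **SiteTable**: per-site, per-group counts of
the derived allele and of called alleles, on (unigene, position)
coordinates. Sites are biallelic SNPs; missing genotypes are excluded from
both the numerator and denominator of every frequency (frequencies are
over called alleles only). Ancestral states are assigned by requiring
*every* polarization outgroup group to be fixed for the same allele at the
site; sites with polymorphic, missing or discordant outgroups are dropped.
This is deliberately conservative: it forfeits sites rather than risk
mispolarized ABBA/BABA patterns, and it forces the pooled outgroup derived
frequency to zero at all surviving sites.

Filters mirror a transcriptome SNP-calling workflow: a 60%-presence rule
(inclusive at the boundary, evaluated across all samples), greedy
first-kept-wins 5-bp thinning within unigenes, an exact test of
Hardy-Weinberg proportions (full enumeration of heterozygote counts at
fixed allele counts, two-sided by probability ordering) applied per
ingroup group, and a BED site-class mask (0-based half-open; VCF positions
are 1-based). Each filter is idempotent and logs in/out counts.

## Introgression statistics

Patterson's D and f_dM are frequency-weighted four-taxon statistics; both
reduce to per-site numerator and denominator terms that are summed over a
unigene's sites, so a unigene's value and any block-resampled value are
ratios of sums. f_dM's denominator is assembled site by site with the
dynamic donor proxy: when p̂₂ ≥ p̂₁ the proxy is the larger of (p̂₂, p̂₃)
substituted into both donor slots; when p̂₂ < p̂₁ the mirrored term
−S(P_D; P₂; P_D; O) is used with the larger of (p̂₁, p̂₃). Ties resolve to
P₃; either choice gives an identical denominator. The per-site denominator
is non-negative and dominates the numerator in magnitude, so f_dM ∈ [−1, 1]
wherever defined. Multiple outgroup groups are pooled into a single
frequency.

### Moving-block bootstrap

Standard errors come from a moving-block bootstrap along the unigene: one
block starts at every site and spans 200 bp (the block size also used for
the d_XY block distributions); a replicate draws blocks uniformly with
replacement until it has covered at least as many sites as the original
gene, and the statistic is recomputed on the concatenated blocks. The
default is 1000 replicates. Two numerical guards matter:

- **Single informative site → SE undefined.** A ratio of sums is invariant
  to how many times a block is redrawn, so if only one site carries a
  nonzero denominator term, every defined replicate returns the identical
  ratio and the naive SE is an artifactual zero. Such genes get SE = NaN
  and drop out of the Z-test family rather than becoming infinitely
  significant.
- **Finite-span bias correction.** On short spans the moving-block SE is
  systematically small: first-order deficits of (1 − b/L) (the span
  fraction one block occupies) and (1 − 1/k) with k = ⌈L/b⌉ non-overlapping
  blocks of degrees of freedom. We verified this factor against an
  iid-site bootstrap on simulated data across spans of 400-2000 bp and
  divide the raw SE by √((1 − b/L)(1 − 1/k)). Spans no longer than one
  block return SE = NaN: a single block's span cannot support an
  autocorrelation-robust variance estimate.

Z-tests are two-tailed against zero with a normal reference,
P = 2Φ(−|value/SE|); the degenerate conventions are P = 0 when SE = 0 with
a nonzero value and P = 1 when both are zero. Benjamini-Hochberg
adjustment is applied within each statistic family (D, f_dM, d_XY) across
all tested unigenes, with missing values passed through.

### The d_XY filter

Introgressed regions show locally *reduced* absolute divergence between
donor and recipient, which shared ancestral polymorphism does not produce.
Since two scalars cannot be "compared statistically", the per-gene test is
interpreted distributionally: the gene's 200-bp-block d_XY values are
compared against the transcriptome-wide pool of block values by a
two-sided Mann-Whitney U test (normal approximation with tie correction;
exact enumeration when both samples have n ≤ 8). Genes whose mean d_XY is
at or above the transcriptome mean are rejected without testing, mirroring
the screen's stated logic; BH adjustment runs over the genes actually
tested. d_XY denominators are SNP-site counts (the table does not record
monomorphic sites); per-bp values can be produced by passing the surveyed
length L explicitly, and diversity statistics likewise report per-SNP
values unless L is given.

## Selection statistics

Weir-Cockerham F_ST is computed at the allele level — alleles as sampled
units, ANOVA variance components MSB and MSW with
n_c = n − Σn_i²/n — because the SiteTable carries allele counts, not
genotypes. Multi-site values are ratios of summed components
(ratio-of-sums), never means of per-site ratios. For PBS, per-gene F_ST is
clamped to [0, 1 − 10⁻⁶] before T = −log(1 − F_ST): negative per-gene
estimates are sampling noise and would otherwise yield negative branch
times, and F_ST = 1 an infinite one. PBS may legitimately be negative.

The HKA-style test counts, per unigene, A = sites segregating within the
target population and B = sites where the target is fixed for one allele
while the control population *and* the HKA outgroup are both fixed for the
other, and tests [[A_gene, B_gene], [A_rest, B_rest]] against the
transcriptome totals by Pearson chi-square (df 1, no continuity
correction); zero-margin tables yield a missing P and exclude the gene
from PSG calling. PSGs are genes at or above the empirical 90th percentile
of defined PBS values (inclusive) with raw HKA P < 0.05 — no FDR here, by
design of the original procedure. Two scans are intended per dataset: the
donor as target and the recipient as target, each against the control,
with a separate congener as the PBS outgroup; admixture-suspect control
samples can be excluded by a configuration list.

## Rare sharing and the overlap null

Rare-SNP sharing uses only sites with complete calls in all three ingroup
groups; the global derived count k (2-5 by default, of 130 pooled alleles
for the default sample sizes) defines the frequency category, and a site is
shared by a pair only if both its members carry the derived allele and the
third group carries none.

The overlap null draws three index sets independently and uniformly
without replacement and records the three-way intersection size. The
implementation samples the intersection through its exact conditional
decomposition — |S₁∩S₂| ~ Hypergeometric(N, s₁, s₂), then
|S₁∩S₂∩S₃| ~ Hypergeometric(N, |S₁∩S₂|, s₃) — which is distributionally
identical to materializing the sets (a test cross-checks this against a
literal set-drawing implementation) and makes 10⁵ replicates essentially
free. The closed-form expectation s₁s₂s₃/N² is exposed for sanity checks.

## The synthetic-data generator

The generator is a verification instrument: it emulates the statistical
structure the scans assume, with exact truth labels, at desk scale. It is
*not* a coalescent simulation — no linkage, recombination, or mutation-age
structure — and conclusions about real-data power do not follow from its
recovery rates alone.

Structure: a rooted tree (((CduN, CduS), Cgi), outgroups) with 65 diploid
ingroup individuals (35/10/20), single-individual polarization outgroups
held fixed ancestral, and a nine-individual selection outgroup. Unigenes
are 200-2000 bp carrying 30-90 planted SNPs (about 30 survive binomial
sampling and filtering, matching the ~30 SNPs per complete-call unigene of
the motivating dataset). Each SNP draws a **mutation-origin class**:

| class | meaning | default weight |
| --- | --- | --- |
| ancestral | shared root polymorphism (the ILS source) | 0.05 |
| CduAnc | variants of the recipient-side lineage | 0.12 |
| Cgi / CduN / CduS / Cch | population-private polymorphism | 0.22 / 0.05 / 0.08 / 0.14 |
| Cgi_sub / Cdu_sub | sorted, near-fixed differences either side of the donor split | 0.24 / 0.10 |

Within its originating subtree a variant drifts down branches under the
Balding-Nichols model (child frequency Beta(p(1−F)/F, (1−p)(1−F)/F); fixed
states stay fixed; F per branch, defaults 0.08-0.40). Spectra: ancestral
Beta(0.25, 2.5), private Beta(0.35, 1.0), substitutions Beta(12, 2).
Introgression is planted at whole unigenes as frequency admixture after
drift, p_CduN ← (1−α)p_CduN + α·p_Cgi with α = 0.9 at 10% of unigenes;
selection pushes the target branch toward the nearer frequency boundary by
0.6 at 4% (donor) and 2% (recipient) of unigenes. Genotypes are
Binomial(2, p) per diploid, missingness is i.i.d. at 2%, ref/alt labels
are randomized so polarization is genuinely exercised, and sites
monomorphic after sampling are dropped, as a SNP caller would.

Design rationale for the class mixture: if every site were ancestrally
polymorphic, per-gene D would be bounded near 0.25-0.4 even at α = 1,
because mid-frequency shared polymorphism feeds ABBA and BABA
symmetrically — no screen with a D ≥ 0.7 gate could ever recover planted
loci, and no d_XY contrast would exist for the ILS filter to use. Real SNP
panels are instead dominated by lineage-specific variants and carry a
backbone of sorted differences; introgression then imports donor-private
alleles (driving D and f_dM) and erases local donor-recipient divergence
(driving the d_XY filter). The weights were calibrated once so that every
screen component carries signal at planted loci while neutral loci stay
null, then frozen. A consequence worth stating plainly: with this
composition the transcriptome-wide ratio-of-sums F_ST between donor and
control sits near 0.78 — one-sided and near-fixed variants dominate the
variance components — which is higher than the modest per-branch drift
values alone would suggest. The pure-ILS null used for type-I calibration
sets the ancestral class weight to 1 with a symmetric Beta(0.8, 0.8)
spectrum, reflecting that standing variation old enough to survive in all
three populations is mid-frequency biased.

What passing tests show: the statistics are implemented correctly (oracle
equivalence to brute-force definitions), the screen recovers planted
tract-level admixture at α = 0.9 with high sensitivity and precision, and
the bootstrap-Z machinery does not flag pure-ILS genes. What they do not
show: power against weaker or older introgression, mosaic (sub-unigene)
tracts, linked selection, reference bias, or genotyping error — none of
which the generator models.

## Pipeline and reproducibility

`run_full` executes the stages in a fixed order, writes one TSV per stage
with a `# key=value` metadata header, and records a `manifest.json` with
input hashes, per-stage seeds, and site counts in/out of every filter
(conservation is asserted in tests). One global seed fans out to per-stage
seeds via `numpy.random.SeedSequence` spawning; the per-unigene bootstrap
seeds are spawned the same way, so results are independent of unigene
iteration order. `--resume` reuses a completed output directory when the
configuration and input hashes match, byte-identically. The overlap test
runs on (introgressed set, donor-PSG set, recipient-PSG set) against the
pool of all tested unigenes.

Problem sizes used by the shipped checks: the recovery study runs 20
seeds × 500 unigenes with 1000 bootstrap replicates per gene; the null
calibration runs 1000 unigenes; the overlap null runs 10⁵ replicates.

## Known limitations

- The Z-test's normal reference remains slightly anticonservative for
  genes whose span supports only two or three blocks (a t-like reference
  with few degrees of freedom would be more faithful); the d_XY filter and
  the BH step absorb this in the screen.
- The HKA implementation is the two-class count contrast of the screening
  procedure, not the original multi-locus likelihood framework.
- θ_π and θ_w are reported per SNP site unless a surveyed length is
  supplied; mixing the two conventions across studies changes absolute
  values but not within-dataset comparisons.
- The d_XY Mann-Whitney compares a gene's blocks against the pooled
  transcriptome blocks including its own; for thousands of genes the
  contamination is negligible.
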