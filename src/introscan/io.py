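"""Genotype data model, site filters, polarization, and SFS construction.

The in-memory substrate of every scan is a :class:`SiteTable`: per-site,
per-group derived-allele counts and called-allele totals on unigene
coordinates, obtained by reading a VCF of biallelic SNPs, applying presence /
spacing / HWE / site-class filters, and polarizing alleles against one or
more outgroup species that must be fixed for the same (ancestral) allele.

Coordinate conventions: VCF POS is 1-based within its unigene (CHROM is the
unigene identifier); BED masks are 0-based half-open.
"""

from __future__ import annotations

import gzip
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .stats import hwe_exact_p

logger = logging.getLogger(__name__)

MISSING = -1  # dosage code for a missing diploid genotype

ROLE_DONOR = "donor"
ROLE_RECIPIENT = "recipient"
ROLE_CONTROL = "control"
ROLE_OUTGROUP_POLARIZE = "outgroup_polarize"
ROLE_OUTGROUP_SELECTION = "outgroup_selection"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class PopulationMap:
    """Sample-to-group assignment plus the analysis role of each group.

    ``assignments`` maps sample id -> group label.  ``roles`` maps a role in
    {donor, recipient, control, outgroup_polarize, outgroup_selection} to a
    group label (outgroup_polarize may name several groups).
    """

    assignments: dict[str, str]
    roles: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for role in (ROLE_DONOR, ROLE_RECIPIENT, ROLE_CONTROL):
            grp = self.roles.get(role)
            if grp is not None and not isinstance(grp, str):
                raise ValueError(f"role {role!r} must map to exactly one group")

    @property
    def groups(self) -> list[str]:
        seen: list[str] = []
        for g in self.assignments.values():
            if g not in seen:
                seen.append(g)
        return seen

    def samples_of(self, group: str) -> list[str]:
        return [s for s, g in self.assignments.items() if g == group]

    def polarize_outgroups(self) -> list[str]:
        out = self.roles.get(ROLE_OUTGROUP_POLARIZE, [])
        if isinstance(out, str):
            out = [out]
        return list(out)

    def exclude(self, samples) -> "PopulationMap":
        """New map with the given samples removed (group roles unchanged)."""
        drop = set(samples)
        return PopulationMap(
            assignments={s: g for s, g in self.assignments.items() if s not in drop},
            roles=dict(self.roles),
        )


@dataclass
class GenotypeMatrix:
    """Biallelic SNP calls: samples x sites alt-allele dosages.

    ``sites`` has columns unigene, pos, ref, alt (pos 1-based within
    unigene); ``calls`` is int8 of shape (n_samples, n_sites) with values in
    {0, 1, 2} or MISSING (-1).  ``unigene_lengths`` carries contig lengths
    from the VCF header when present.
    """

    samples: list[str]
    sites: pd.DataFrame
    calls: np.ndarray
    unigene_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.calls.shape != (len(self.samples), len(self.sites)):
            raise ValueError("calls shape does not match samples x sites")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def take_sites(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return replace(
            self,
            sites=self.sites.iloc[idx].reset_index(drop=True),
            calls=self.calls[:, idx],
        )


@dataclass
class SiteTable:
    """Polarized per-site, per-group derived-allele counts.

    ``derived`` and ``called`` are int arrays of shape (n_groups, n_sites):
    copies of the derived allele among called alleles, and called alleles,
    per group.  ``group_sizes`` is the diploid sample count per group (the
    ceiling of ``called`` is 2 x group size).
    """

    sites: pd.DataFrame  # unigene, pos, ref, alt, ancestral, derived_allele
    groups: list[str]
    derived: np.ndarray
    called: np.ndarray
    group_sizes: dict[str, int]
    unigene_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(self.derived > self.called):
            raise ValueError("derived count exceeds called alleles")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def _gi(self, group: str) -> int:
        return self.groups.index(group)

    def freq(self, group: str) -> np.ndarray:
        """Derived-allele frequency per site; NaN where no alleles called."""
        i = self._gi(group)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(
                self.called[i] > 0, self.derived[i] / self.called[i], np.nan
            )

    def pooled_freq(self, groups) -> np.ndarray:
        """Derived frequency with several groups pooled into one."""
        idx = [self._gi(g) for g in groups]
        der = self.derived[idx].sum(axis=0)
        cal = self.called[idx].sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(cal > 0, der / cal, np.nan)

    def counts(self, group: str) -> tuple[np.ndarray, np.ndarray]:
        i = self._gi(group)
        return self.derived[i], self.called[i]

    def take_sites(self, idx) -> "SiteTable":
        idx = np.asarray(idx)
        return replace(
            self,
            sites=self.sites.iloc[idx].reset_index(drop=True),
            derived=self.derived[:, idx],
            called=self.called[:, idx],
        )


@dataclass
class SFS:
    """A (possibly multidimensional) site frequency spectrum."""

    dims: list[str]
    counts: np.ndarray
    folded: bool

    @property
    def n_sites(self) -> float:
        return float(self.counts.sum())

    def marginal(self, group: str) -> np.ndarray:
        axis = tuple(i for i, g in enumerate(self.dims) if g != group)
        return self.counts.sum(axis=axis)


def unigene_index(sites: pd.DataFrame) -> dict[str, np.ndarray]:
    """unigene id -> array of site row indices ordered by position.

    Assumes (and enforces) that (unigene, pos) pairs are unique.
    """
    if sites.duplicated(["unigene", "pos"]).any():
        raise ValueError("duplicate (unigene, pos) coordinates")
    order = np.lexsort((sites["pos"].to_numpy(), sites["unigene"].to_numpy()))
    index: dict[str, np.ndarray] = {}
    uni = sites["unigene"].to_numpy()[order]
    for u in pd.unique(uni):
        index[u] = order[uni == u]
    return index


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_popmap(path) -> dict[str, str]:
    """Read a two-column sample<TAB>group TSV."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "group"],
                     dtype=str, comment="#")
    return dict(zip(df["sample"], df["group"]))


def read_vcf(path, popmap: PopulationMap | None = None) -> GenotypeMatrix:
    """Load biallelic SNP records from a VCF (v4.x, optionally gzipped).

    Multiallelic and indel records are skipped (counts logged).  Raises if a
    popmap sample is absent from the VCF header.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    if popmap is not None:
        missing = [s for s in popmap.assignments if s not in samples]
        if missing:
            raise ValueError(
                f"samples in population map but not in VCF: {', '.join(missing)}"
            )
    lengths: dict[str, int] = {}
    try:
        lengths = dict(zip(vcf.seqnames, vcf.seqlens))
    except Exception:  # header without contig lengths
        lengths = {}

    rows = []
    calls = []
    n_skipped = 0
    for v in vcf:
        if len(v.ALT) != 1 or not v.is_snp:
            n_skipped += 1
            continue
        # gts012: 0 hom-ref, 1 het, 2 hom-alt, 3 unknown
        g = v.gt_types.astype(np.int8)
        g[g == 3] = MISSING
        rows.append((v.CHROM, v.POS, v.REF, v.ALT[0]))
        calls.append(g)
    if n_skipped:
        logger.info("read_vcf: skipped %d multiallelic/indel records", n_skipped)
    sites = pd.DataFrame(rows, columns=["unigene", "pos", "ref", "alt"])
    arr = (
        np.asarray(calls, dtype=np.int8).T
        if calls
        else np.empty((len(samples), 0), dtype=np.int8)
    )
    gm = GenotypeMatrix(samples=samples, sites=sites, calls=arr,
                        unigene_lengths=lengths)
    gm.n_skipped_records = n_skipped
    return gm


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write the matrix as a minimal GT-only VCF v4.2."""
    opener = gzip.open if str(path).endswith(".gz") else open
    code = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with opener(str(path), "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=introscan\n")
        for u in pd.unique(gm.sites["unigene"]):
            length = gm.unigene_lengths.get(u)
            if length:
                fh.write(f"##contig=<ID={u},length={length}>\n")
            else:
                fh.write(f"##contig=<ID={u}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.samples) + "\n")
        sites = gm.sites.itertuples(index=False)
        for j, s in enumerate(sites):
            gts = "\t".join(code[int(d)] for d in gm.calls[:, j])
            fh.write(f"{s.unigene}\t{s.pos}\t.\t{s.ref}\t{s.alt}\t.\tPASS\t.\tGT\t{gts}\n")


def read_bed_mask(path) -> dict[str, np.ndarray]:
    """Read a BED file into contig -> (n, 2) array of [start, end) intervals."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2], names=["chrom", "start", "end"])
    out: dict[str, np.ndarray] = {}
    for chrom, sub in df.groupby("chrom"):
        out[str(chrom)] = sub[["start", "end"]].to_numpy(dtype=np.int64)
    return out


# ---------------------------------------------------------------------------
# site filters
# ---------------------------------------------------------------------------

def filter_missingness(gm: GenotypeMatrix, min_presence: float = 0.6) -> GenotypeMatrix:
    """Keep sites called in at least ``min_presence`` of all samples.

    The boundary is inclusive: a site present in exactly 60% of samples is
    retained under the default.
    """
    if not 0 < min_presence <= 1:
        raise ValueError("min_presence must lie in (0, 1]")
    if gm.n_sites == 0:
        raise ValueError("empty genotype matrix")
    present = (gm.calls != MISSING).sum(axis=0) / len(gm.samples)
    keep = np.nonzero(present >= min_presence - 1e-12)[0]
    return gm.take_sites(keep)


def thin_sites(gm: GenotypeMatrix, min_spacing_bp: int = 5) -> GenotypeMatrix:
    """Greedy per-unigene thinning: keep a site iff it lies more than
    ``min_spacing_bp`` beyond the last kept site of the same unigene."""
    keep: list[int] = []
    for _, idx in unigene_index(gm.sites).items():
        last = None
        pos = gm.sites["pos"].to_numpy()
        for i in idx:
            if last is None or pos[i] - last > min_spacing_bp:
                keep.append(i)
                last = pos[i]
    keep = np.sort(np.asarray(keep, dtype=np.int64))
    return gm.take_sites(keep)


def hwe_filter(
    gm: GenotypeMatrix,
    popmap: PopulationMap,
    groups,
    alpha: float = 0.05,
) -> GenotypeMatrix:
    """Drop sites deviating from Hardy-Weinberg proportions in any listed
    group (exact test, P < alpha).  Groups with zero called genotypes at a
    site pass by convention."""
    sample_idx = {s: i for i, s in enumerate(gm.samples)}
    keep = np.ones(gm.n_sites, dtype=bool)
    for group in groups:
        rows = [sample_idx[s] for s in popmap.samples_of(group)]
        sub = gm.calls[rows]
        for j in range(gm.n_sites):
            col = sub[:, j]
            called = col[col != MISSING]
            if called.size == 0:
                continue
            n_het = int((called == 1).sum())
            n_alt = int((called == 2).sum())
            n_ref = called.size - n_het - n_alt
            if hwe_exact_p(n_ref, n_het, n_alt) < alpha:
                keep[j] = False
    return gm.take_sites(np.nonzero(keep)[0])


def apply_site_mask(gm: GenotypeMatrix, mask: dict[str, np.ndarray]) -> GenotypeMatrix:
    """Keep sites whose 0-based position falls in a mask interval of the same
    unigene (BED semantics).  Mask contigs absent from the data are ignored
    with a warning."""
    unseen = set(mask) - set(gm.sites["unigene"])
    if unseen:
        warnings.warn(
            f"mask contigs absent from data: {', '.join(sorted(unseen))}",
            stacklevel=2,
        )
    keep = np.zeros(gm.n_sites, dtype=bool)
    pos0 = gm.sites["pos"].to_numpy() - 1
    uni = gm.sites["unigene"].to_numpy()
    for u, ivals in mask.items():
        sel = uni == u
        if not sel.any():
            continue
        p = pos0[sel]
        inside = np.zeros(p.shape, dtype=bool)
        for start, end in ivals:
            inside |= (p >= start) & (p < end)
        keep[np.nonzero(sel)[0][inside]] = True
    if not keep.any():
        warnings.warn("site mask removed every site", stacklevel=2)
    return gm.take_sites(np.nonzero(keep)[0])


# ---------------------------------------------------------------------------
# polarization
# ---------------------------------------------------------------------------

def polarize(gm: GenotypeMatrix, popmap: PopulationMap) -> SiteTable:
    """Assign ancestral states from the polarization outgroups and tabulate
    per-group derived-allele counts.

    The ancestral allele is the allele fixed and identical across every
    polarization outgroup group.  Sites where any outgroup group is
    polymorphic, entirely missing, or where the outgroups disagree are
    dropped (count logged).
    """
    outgroups = popmap.polarize_outgroups()
    if not outgroups:
        raise ValueError("population map defines no polarization outgroup")
    sample_idx = {s: i for i, s in enumerate(gm.samples)}

    # per outgroup group: fixed-state code per site (0 ref, 1 alt, -9 invalid)
    states = []
    for og in outgroups:
        rows = [sample_idx[s] for s in popmap.samples_of(og)]
        sub = gm.calls[rows]
        called = sub != MISSING
        n_called = called.sum(axis=0)
        alt_copies = np.where(called, sub, 0).sum(axis=0)
        state = np.full(gm.n_sites, -9, dtype=np.int8)
        state[(n_called > 0) & (alt_copies == 0)] = 0
        state[(n_called > 0) & (alt_copies == 2 * n_called)] = 1
        states.append(state)
    states = np.vstack(states)
    ok = np.all(states >= 0, axis=0) & np.all(states == states[0], axis=0)
    anc_is_alt = states[0] == 1

    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("polarize: dropped %d sites (outgroup polymorphic/missing/discordant)",
                    n_dropped)

    keep = np.nonzero(ok)[0]
    groups = popmap.groups
    derived = np.zeros((len(groups), keep.size), dtype=np.int64)
    called_alleles = np.zeros_like(derived)
    for gi, group in enumerate(groups):
        rows = [sample_idx[s] for s in popmap.samples_of(group)]
        sub = gm.calls[np.ix_(rows, keep)]
        mask = sub != MISSING
        called_alleles[gi] = 2 * mask.sum(axis=0)
        alt_copies = np.where(mask, sub, 0).sum(axis=0)
        # derived allele is alt where ancestral is ref, and vice versa
        derived[gi] = np.where(
            anc_is_alt[keep], called_alleles[gi] - alt_copies, alt_copies
        )

    sites = gm.sites.iloc[keep].reset_index(drop=True).copy()
    anc = np.where(anc_is_alt[keep], sites["alt"], sites["ref"])
    der = np.where(anc_is_alt[keep], sites["ref"], sites["alt"])
    sites["ancestral"] = anc
    sites["derived_allele"] = der

    st = SiteTable(
        sites=sites,
        groups=groups,
        derived=derived,
        called=called_alleles,
        group_sizes={g: len(popmap.samples_of(g)) for g in groups},
        unigene_lengths=dict(gm.unigene_lengths),
    )
    st.n_dropped = n_dropped
    return st


# ---------------------------------------------------------------------------
# site frequency spectra
# ---------------------------------------------------------------------------

def build_sfs(st: SiteTable, groups, folded: bool = False) -> SFS:
    """Tabulate the (multidimensional) SFS over the listed groups.

    Only sites with complete calls in every listed group contribute (the
    convention of demographic-inference inputs).  Unfolded cells are indexed
    by derived count per group; folding maps a cell to its minor-allele
    mirror, splitting weight equally when a site sits exactly at half
    frequency.
    """
    groups = list(groups)
    sizes = [2 * st.group_sizes[g] for g in groups]
    idx = [st._gi(g) for g in groups]
    complete = np.all(
        st.called[idx] == np.array(sizes)[:, None], axis=0
    )
    ks = st.derived[idx][:, complete]  # (n_groups, n_complete_sites)

    shape = tuple(s + 1 for s in sizes)
    counts = np.zeros(shape, dtype=float)
    np.add.at(counts, tuple(ks), 1.0)
    if not folded:
        return SFS(dims=groups, counts=counts, folded=False)

    total = ks.sum(axis=0)
    half = sum(sizes) / 2.0
    folded_counts = np.zeros(shape, dtype=float)
    mirror = np.array(sizes)[:, None] - ks
    upper = total > half
    at_half = total == half
    lower = ~(upper | at_half)
    for sel, cells, w in (
        (lower, ks, 1.0),
        (upper, mirror, 1.0),
        (at_half, ks, 0.5),
        (at_half, mirror, 0.5),
    ):
        if sel.any():
            np.add.at(folded_counts, tuple(cells[:, sel]), w)
    return SFS(dims=groups, counts=folded_counts, folded=True)


def write_sfs_dadi(sfs: SFS, path) -> None:
    """Plain-text SFS: shape ints plus 'folded'/'unfolded' on line 1, the
    flattened (C-order) counts on line 2, and a 0/1 mask line (all zeros)."""
    with open(str(path), "w") as fh:
        shape = " ".join(str(s) for s in sfs.counts.shape)
        fh.write(f"{shape} {'folded' if sfs.folded else 'unfolded'}\n")
        fh.write(" ".join(format(x, "g") for x in sfs.counts.ravel()) + "\n")
        fh.write(" ".join("0" for _ in range(sfs.counts.size)) + "\n")


def write_sfs_fsc(sfs: SFS, path, label: str = "obs") -> None:
    """Multidimensional .obs dialect: a '1 observations' header, a line with
    the number of demes and per-deme haploid sizes, then the flattened
    (C-order) counts."""
    with open(str(path), "w") as fh:
        fh.write(f"1 observations. {label}\n")
        sizes = " ".join(str(s - 1) for s in sfs.counts.shape)
        fh.write(f"{len(sfs.dims)} {sizes}\n")
        fh.write("\t".join(format(x, "g") for x in sfs.counts.ravel()) + "\n")
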