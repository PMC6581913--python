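import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from introscan.io import GenotypeMatrix, PopulationMap, SiteTable

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def tiny_popmap():
    """Three diploids per ingroup, one per polarization outgroup."""
    assignments = {}
    for grp, n in (("Cgi", 3), ("CduN", 3), ("CduS", 3), ("Cfu", 1), ("Jmi", 1)):
        for i in range(n):
            assignments[f"{grp}_{i}"] = grp
    return PopulationMap(
        assignments=assignments,
        roles={
            "donor": "Cgi",
            "recipient": "CduN",
            "control": "CduS",
            "outgroup_polarize": ["Cfu", "Jmi"],
        },
    )


def make_gm(sites, calls, samples):
    df = pd.DataFrame(sites, columns=["unigene", "pos", "ref", "alt"])
    return GenotypeMatrix(
        samples=samples,
        sites=df,
        calls=np.asarray(calls, dtype=np.int8),
    )


def make_site_table(derived, called, groups, group_sizes, pos=None, unigene=None):
    """Bare SiteTable from count arrays, for direct statistic tests."""
    derived = np.atleast_2d(np.asarray(derived))
    called = np.atleast_2d(np.asarray(called))
    n_sites = derived.shape[1]
    sites = pd.DataFrame({
        "unigene": unigene if unigene is not None else ["g1"] * n_sites,
        "pos": pos if pos is not None else np.arange(1, n_sites + 1),
        "ref": "A",
        "alt": "T",
        "ancestral": "A",
        "derived_allele": "T",
    })
    return SiteTable(
        sites=sites,
        groups=list(groups),
        derived=derived.astype(np.int64),
        called=called.astype(np.int64),
        group_sizes=dict(group_sizes),
    )


@pytest.fixture
def small_sim():
    """Session-cheap simulated dataset with planted truth."""
    from introscan.simulate import SimConfig, simulate_dataset

    cfg = SimConfig(n_unigenes=60, seed=5)
    gm, popmap, truth = simulate_dataset(cfg)
    return gm, popmap, truth
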