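"""D statistic, f_dM, moving-block bootstrap, and the candidate screen."""

import numpy as np
import pandas as pd
import pytest

from introscan.introgression import (
    QuartetSpec,
    ScanResult,
    block_bootstrap_se,
    d_statistic,
    f_dm,
    moving_blocks,
    scan_unigenes,
    screen_introgressed,
    site_terms,
)
from tests.conftest import make_site_table

QUARTET = QuartetSpec(p1="P1", p2="P2", p3="P3", outgroups=["O"])
GROUPS = ["P1", "P2", "P3", "O"]
SIZES = {"P1": 10, "P2": 10, "P3": 10, "O": 1}


def table_from_freqs(freqs, n_alleles=20, pos=None, unigene=None):
    """SiteTable whose sampled frequencies equal the given quartet freqs."""
    freqs = np.asarray(freqs, dtype=float)  # (n_sites, 4)
    derived = np.round(freqs.T * n_alleles).astype(int)
    derived[3] = np.round(freqs[:, 3] * 2).astype(int)  # outgroup: 1 diploid
    called = np.full_like(derived, n_alleles)
    called[3] = 2
    return make_site_table(derived, called, GROUPS, SIZES, pos=pos,
                           unigene=unigene)


def d_oracle(freqs):
    """Per-site loop transcription of the D definition."""
    abba = baba = 0.0
    for p1, p2, p3, p4 in freqs:
        abba += (1 - p1) * p2 * p3 * (1 - p4)
        baba += p1 * (1 - p2) * p3 * (1 - p4)
    return (abba - baba) / (abba + baba)


def fdm_oracle(freqs):
    """Per-site loop transcription of the published f_dM conditional."""
    def s_term(pa, pb, pc, pd):
        return (1 - pa) * pb * pc * (1 - pd) - pa * (1 - pb) * pc * (1 - pd)

    num = den = 0.0
    for p1, p2, p3, p4 in freqs:
        num += s_term(p1, p2, p3, p4)
        if p2 >= p1:
            pd_ = p3 if p3 >= p2 else p2
            den += s_term(p1, pd_, pd_, p4)
        else:
            pd_ = p3 if p3 >= p1 else p1
            den += -s_term(pd_, p2, pd_, p4)
    return num / den


class TestDStatistic:
    def test_pure_abba(self):
        st = table_from_freqs([(0, 1, 1, 0)])
        _, _, d = d_statistic(st, QUARTET)
        assert d == pytest.approx(1.0)

    def test_balanced(self):
        st = table_from_freqs([(0, 1, 1, 0), (1, 0, 1, 0)])
        assert d_statistic(st, QUARTET)[2] == pytest.approx(0.0)

    def test_two_to_one(self):
        st = table_from_freqs([(0, 1, 1, 0), (0, 1, 1, 0), (1, 0, 1, 0)])
        assert d_statistic(st, QUARTET)[2] == pytest.approx(1 / 3)

    def test_undefined_when_denominator_zero(self):
        st = table_from_freqs([(0, 0, 0, 0)])
        assert np.isnan(d_statistic(st, QUARTET)[2])

    def test_matches_bruteforce_on_random_tables(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            n = rng.integers(5, 100)
            freqs = rng.integers(0, 21, size=(n, 4)) / 20
            freqs[:, 3] = rng.integers(0, 3, size=n) / 2
            st = table_from_freqs(freqs)
            assert d_statistic(st, QUARTET)[2] == pytest.approx(
                d_oracle(freqs), rel=1e-10
            )

    def test_swap_p1_p2_negates(self):
        rng = np.random.default_rng(10)
        freqs = rng.integers(0, 21, size=(30, 4)) / 20
        freqs[:, 3] = 0
        st = table_from_freqs(freqs)
        swapped = QuartetSpec(p1="P2", p2="P1", p3="P3", outgroups=["O"])
        assert d_statistic(st, QUARTET)[2] == pytest.approx(
            -d_statistic(st, swapped)[2]
        )


class TestFdm:
    def test_complete_sharing(self):
        st = table_from_freqs([(0, 0.5, 0.5, 0)])
        assert f_dm(st, QUARTET) == pytest.approx(1.0)

    def test_complete_reversal(self):
        # mirrored conditional: S = -0.25 and the p2 < p1 branch gives
        # denominator 0.25
        st = table_from_freqs([(0.5, 0, 0.5, 0)])
        assert f_dm(st, QUARTET) == pytest.approx(-1.0)

    def test_zero_when_donor_absent(self):
        st = table_from_freqs([(0.5, 0.25, 0, 0), (0.2, 0.6, 0, 0)])
        assert f_dm(st, QUARTET) == pytest.approx(0.0)

    def test_equal_p2_p3_above_p1_gives_one(self):
        rng = np.random.default_rng(2)
        p1 = rng.uniform(0, 0.4, 10)
        p23 = rng.uniform(0.45, 1.0, 10)
        freqs = np.column_stack([p1, p23, p23, np.zeros(10)])
        num = site_terms(*freqs.T)[2].sum()
        den = site_terms(*freqs.T)[3].sum()
        assert num / den == pytest.approx(1.0)

    def test_bounded_on_random_quartets(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(size=(100_000, 4))
        _, _, num, den = site_terms(p[:, 0], p[:, 1], p[:, 2], p[:, 3])
        assert np.all(np.abs(num) <= den + 1e-12)

    def test_matches_bruteforce_on_random_tables(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            n = int(rng.integers(5, 100))
            freqs = rng.integers(0, 21, size=(n, 4)) / 20
            freqs[:, 3] = 0
            st = table_from_freqs(freqs)
            assert f_dm(st, QUARTET) == pytest.approx(
                fdm_oracle(freqs), rel=1e-10
            )


class TestMovingBlocks:
    def test_block_membership(self):
        pos = np.array([100, 150, 299, 300, 600])
        blocks = moving_blocks(pos, 200)
        # block starting at 100 covers [100, 300): sites 100, 150, 299
        assert blocks[0].tolist() == [0, 3]
        assert blocks[3].tolist() == [3, 4]
        assert blocks[4].tolist() == [4, 5]


class TestBlockBootstrap:
    def test_uniform_pattern_zero_se(self):
        # identical pure-ABBA pattern throughout: every replicate returns the
        # point estimate
        freqs = [(0, 1, 1, 0)] * 12
        pos = np.arange(1, 13) * 150
        st = table_from_freqs(freqs, pos=pos)
        se = block_bootstrap_se(st, QUARTET, np.arange(12), "D", n_boot=200,
                                seed=0)
        assert se == 0.0

    def test_single_informative_site_undefined(self):
        freqs = [(0, 1, 1, 0)] + [(0, 0, 0, 0)] * 9
        pos = np.arange(1, 11) * 150
        st = table_from_freqs(freqs, pos=pos)
        se = block_bootstrap_se(st, QUARTET, np.arange(10), "D", n_boot=200,
                                seed=0)
        assert np.isnan(se)

    def test_short_span_undefined(self):
        freqs = [(0, 1, 1, 0), (1, 0, 1, 0)]
        st = table_from_freqs(freqs, pos=np.array([10, 60]))
        se = block_bootstrap_se(st, QUARTET, np.arange(2), "D", n_boot=200,
                                seed=0)
        assert np.isnan(se)

    def test_two_block_toy_matches_enumeration(self):
        """Two equal-size blocks with D = +1 and -1: replicates draw two
        blocks, giving D in {1, 0, -1} with probabilities 1/4, 1/2, 1/4."""
        freqs = [(0, 1, 1, 0), (1, 0, 1, 0)]
        pos = np.array([100, 401])  # span 302 -> two disjoint blocks
        st = table_from_freqs(freqs, pos=pos)
        outcomes = np.array([1.0, 0.0, 0.0, -1.0])
        sd = np.std(outcomes)  # closed-form SD of the resample distribution
        span = 302
        correction = np.sqrt((1 - 200 / span) * (1 - 1 / np.ceil(span / 200)))
        expected = sd / correction
        se = block_bootstrap_se(st, QUARTET, np.arange(2), "D",
                                n_boot=40_000, seed=3)
        assert se == pytest.approx(expected, rel=0.03)


class TestScreen:
    def _scan_result(self, d_values, p=1e-6):
        genes = [f"g{i}" for i in range(len(d_values))]
        table = pd.DataFrame({
            "unigene": genes,
            "n_sites_used": 10,
            "abba_sum": 1.0,
            "baba_sum": 0.1,
            "D": d_values,
            "f_dM": 0.5,
            "se_D": 0.05,
            "se_f": 0.05,
            "p_D": p,
            "p_f": p,
            "dxy_gene": 0.05,
        })
        block_gene = {g: np.full(12, 0.05) for g in genes}
        return ScanResult(
            table=table,
            dxy_transcriptome_mean=0.2,
            block_dxy_all=np.concatenate(
                [np.full(300, 0.25), np.full(12, 0.05)]
            ),
            block_dxy_gene=block_gene,
        )

    def test_threshold_strict_below(self):
        out = screen_introgressed(self._scan_result([0.69, 0.9]))
        assert not out.loc[out.unigene == "g0", "candidate"].item()

    def test_threshold_inclusive_at_0_7(self):
        out = screen_introgressed(self._scan_result([0.7, 0.9]))
        assert out.loc[out.unigene == "g0", "candidate"].item()

    def test_high_dxy_rejected_without_testing(self):
        res = self._scan_result([0.9])
        res.table.loc[0, "dxy_gene"] = 0.3  # above the transcriptome mean
        out = screen_introgressed(res)
        assert not out.candidate.item()
        assert np.isnan(out.p_dxy.item())

    def test_missing_transcriptome_mean_rejected(self):
        res = self._scan_result([0.9])
        res.dxy_transcriptome_mean = float("nan")
        with pytest.raises(ValueError):
            screen_introgressed(res)


def test_recovery_on_planted_dataset(small_sim):
    """The full scan recovers most planted introgressed unigenes in a small
    simulated transcriptome without false calls among neutral genes."""
    from introscan import io as iom

    gm, popmap, truth = small_sim
    st = iom.polarize(iom.filter_missingness(gm), popmap)
    res = scan_unigenes(st, QuartetSpec.from_popmap(popmap), n_boot=300,
                        seed=7)
    out = screen_introgressed(res)
    planted = set(truth.unigenes_with("introgressed"))
    called = set(out.loc[out.candidate, "unigene"])
    assert len(called & planted) >= 0.5 * len(planted)
    assert not (called - planted)
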