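"""Diversity and differentiation statistics against brute-force oracles."""

import numpy as np
import pytest

from introscan.popgen import (
    dxy,
    fst_wc,
    fst_wc_components,
    harmonic_number,
    mutation_rate,
    theta_pi,
)
from tests.conftest import make_site_table


def wc_fst_oracle(k1, n1, k2, n2):
    """Straight-from-the-variance-components two-population estimator,
    written as explicit per-site loops (alleles as sampled units)."""
    num_t = den_t = 0.0
    for a1, m1, a2, m2 in zip(k1, n1, k2, n2):
        if m1 < 2 or m2 < 2:
            continue
        p1, p2 = a1 / m1, a2 / m2
        n = m1 + m2
        pbar = (a1 + a2) / n
        msb = m1 * (p1 - pbar) ** 2 + m2 * (p2 - pbar) ** 2
        msw = (m1 * p1 * (1 - p1) + m2 * p2 * (1 - p2)) / (n - 2)
        nc = n - (m1 ** 2 + m2 ** 2) / n
        num_t += msb - msw
        den_t += msb + (nc - 1) * msw
    return num_t / den_t


class TestThetaPi:
    def test_single_pair_difference(self):
        st = make_site_table([1], [2], ["g"], {"g": 1})
        rec = theta_pi(st, "g", L=100)
        assert rec.theta_pi == pytest.approx(1 / 100)

    def test_monomorphic_contributes_zero(self):
        st = make_site_table([0, 1], [2, 2], ["g"], {"g": 1})
        rec = theta_pi(st, "g", L=1)
        assert rec.theta_pi == pytest.approx(1.0)  # only the k=1 site counts

    def test_pairwise_average_oracle(self):
        # k=2 of n=4: 4 of the 6 sequence pairs differ -> 2/3 per site
        pairs_differing = sum(
            1 for i in range(4) for j in range(i + 1, 4)
            if (i < 2) != (j < 2)
        )
        expected = pairs_differing / 6
        st = make_site_table([2], [4], ["g"], {"g": 2})
        assert theta_pi(st, "g", L=1).theta_pi == pytest.approx(expected)


class TestThetaW:
    def test_direct_formula(self):
        ks = [1] * 11
        st = make_site_table(ks, [4] * 11, ["g"], {"g": 2})
        rec = theta_pi(st, "g", L=1000)
        a4 = 1 + 1 / 2 + 1 / 3
        assert rec.theta_w == pytest.approx(11 / (a4 * 1000))
        assert rec.S == 11

    def test_no_segregating_sites(self):
        st = make_site_table([0, 4], [4, 4], ["g"], {"g": 2})
        assert theta_pi(st, "g", L=10).theta_w == 0.0

    def test_two_alleles_limit(self):
        st = make_site_table([1, 1, 1], [2, 2, 2], ["g"], {"g": 1})
        rec = theta_pi(st, "g", L=50)
        assert harmonic_number(2) == 1.0
        assert rec.theta_w == pytest.approx(3 / 50)


class TestFst:
    def test_no_differentiation_near_zero(self):
        rng = np.random.default_rng(0)
        k = rng.integers(5, 35, size=200)
        st = make_site_table([k, k], [[40] * 200] * 2, ["a", "b"],
                             {"a": 20, "b": 20})
        rec = fst_wc(st, "a", "b")
        assert abs(rec.fst) < 0.05

    def test_fixed_difference(self):
        st = make_site_table([[0], [20]], [[20], [20]], ["a", "b"],
                             {"a": 10, "b": 10})
        assert fst_wc(st, "a", "b").fst == pytest.approx(1.0)

    def test_single_site_oracle(self):
        st = make_site_table([[5], [15]], [[20], [20]], ["a", "b"],
                             {"a": 10, "b": 10})
        assert fst_wc(st, "a", "b").fst == pytest.approx(
            wc_fst_oracle([5], [20], [15], [20]), rel=1e-12
        )

    def test_ratio_of_sums_oracle_random(self):
        rng = np.random.default_rng(7)
        n_sites = 80
        n1 = rng.integers(4, 40, n_sites)
        n2 = rng.integers(4, 40, n_sites)
        k1 = rng.integers(0, n1 + 1)
        k2 = rng.integers(0, n2 + 1)
        st = make_site_table([k1, k2], [n1, n2], ["a", "b"], {"a": 20, "b": 20})
        assert fst_wc(st, "a", "b").fst == pytest.approx(
            wc_fst_oracle(k1, n1, k2, n2), rel=1e-10
        )

    def test_permuted_labels_near_zero(self):
        """Random reallocation of pooled allele counts behaves like no
        structure."""
        rng = np.random.default_rng(3)
        totals_k = rng.integers(10, 50, 300)
        totals_n = np.full(300, 80)
        k1 = rng.hypergeometric(totals_k, totals_n - totals_k, 40)
        st = make_site_table([k1, totals_k - k1], [[40] * 300] * 2,
                             ["a", "b"], {"a": 20, "b": 20})
        assert abs(fst_wc(st, "a", "b").fst) < 0.03


class TestDxy:
    def test_fixed_difference(self):
        st = make_site_table([[0], [4]], [[4], [4]], ["a", "b"],
                             {"a": 2, "b": 2})
        assert dxy(st, "a", "b", L=100).dxy == pytest.approx(1 / 100)

    def test_equal_frequencies_identity(self):
        k = np.array([1, 2, 3])
        st = make_site_table([k, k], [[4] * 3] * 2, ["a", "b"],
                             {"a": 2, "b": 2})
        p = k / 4
        expected = np.mean(2 * p * (1 - p))
        assert dxy(st, "a", "b").dxy == pytest.approx(expected)

    def test_half_half(self):
        st = make_site_table([[2], [2]], [[4], [4]], ["a", "b"],
                             {"a": 2, "b": 2})
        assert dxy(st, "a", "b", L=1).dxy == pytest.approx(0.5)

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        k1 = rng.integers(0, 5, 20)
        k2 = rng.integers(0, 5, 20)
        st = make_site_table([k1, k2], [[4] * 20] * 2, ["a", "b"],
                             {"a": 2, "b": 2})
        assert dxy(st, "a", "b").dxy == pytest.approx(dxy(st, "b", "a").dxy)


class TestMutationRate:
    def test_paper_parameterization(self):
        # mu = D g / 2T at g = 50 y, T = 62.8 My reproduces 7.0e-9 when D is
        # inverted from that rate
        d = 7.0e-9 * 2 * 62.8e6 / 50
        assert d == pytest.approx(0.017584)
        assert mutation_rate(d, 50, 62.8e6) == pytest.approx(7.0e-9)

    def test_linearity_in_g(self):
        assert mutation_rate(0.01, 100, 1e6) == pytest.approx(
            2 * mutation_rate(0.01, 50, 1e6)
        )

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            mutation_rate(0.0, 50, 1e6)


def test_theta_pi_theta_w_agree_under_neutral_sim():
    """Under the neutral generator the two estimators target the same theta;
    their ratio should be of order one over many sites."""
    from introscan import io as iom
    from introscan.simulate import SimConfig, simulate_dataset

    cfg = SimConfig(n_unigenes=250, introgressed_fraction=0.0,
                    admixture_alpha=0.0, selected_fraction=0.0,
                    selected_recipient_fraction=0.0, seed=42,
                    origin_weights={"ancestral": 1.0},
                    ancestral_freq_beta=(0.8, 0.8))
    gm, popmap, _ = simulate_dataset(cfg)
    st = iom.polarize(iom.filter_missingness(gm), popmap)
    assert st.n_sites >= 10_000
    rec = theta_pi(st, "Cgi")
    ratio = rec.theta_pi / rec.theta_w
    assert 0.5 < ratio < 2.0
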