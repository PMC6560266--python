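"""Window statistics against independent oracles and analytic cases."""
import numpy as np
import pandas as pd
import pytest

import oracles
from convergescan import stats
from convergescan.model import AlleleCounts


def counts_from_arrays(alt_by_pop, called_by_pop, pops=("A", "B"),
                       polarized=True):
    alt = np.asarray(alt_by_pop)
    called = np.asarray(called_by_pop)
    return AlleleCounts(
        populations=list(pops[:alt.shape[0]]), alt=alt, called=called,
        derived=alt.copy(), polarized=np.ones(alt.shape[1], bool),
        ancestral_is_ref=np.ones(alt.shape[1], bool))


def one_window(n_sites):
    return np.arange(n_sites)[None, :]


class TestDiversity:
    def test_single_site_pi(self):
        c = counts_from_arrays([[1]], [[4]], pops=("A",))
        pi, theta, _ = stats.window_diversity(c, one_window(1), "A")
        assert pi[0] == pytest.approx(0.5)
        assert pi[0] == pytest.approx(oracles.pi_site_bruteforce(1, 4))

    def test_monomorphic_window_is_zero(self):
        c = counts_from_arrays([[0, 4, 0]], [[4, 4, 4]], pops=("A",))
        pi, theta, _ = stats.window_diversity(c, one_window(3), "A")
        assert pi[0] == pytest.approx(2 / 3 * oracles.pi_site_bruteforce(4, 4))
        c2 = counts_from_arrays([[0, 0, 0]], [[4, 4, 4]], pops=("A",))
        pi2, theta2, _ = stats.window_diversity(c2, one_window(3), "A")
        assert pi2[0] == 0.0 and theta2[0] == 0.0

    def test_window_pi_matches_pairwise_bruteforce(self):
        rng = np.random.default_rng(0)
        n = 12
        alt = rng.integers(0, n + 1, 25)
        c = counts_from_arrays([alt], [np.full(25, n)], pops=("A",))
        pi, _, _ = stats.window_diversity(c, one_window(25), "A")
        assert pi[0] == pytest.approx(
            oracles.pi_window_bruteforce(alt, np.full(25, n)), abs=1e-12)


class TestTajimasD:
    def test_zero_when_pi_equals_theta(self):
        # find a configuration with pi_total == theta_total is fiddly;
        # instead check the numerator directly through the oracle
        rng = np.random.default_rng(1)
        alt = rng.integers(1, 9, 25)
        c = counts_from_arrays([alt], [np.full(25, 10)], pops=("A",))
        d = stats.tajimas_d(c, one_window(25), "A")
        assert d[0] == pytest.approx(
            oracles.tajimas_d_textbook(alt, np.full(25, 10)), abs=1e-10)

    def test_singleton_excess_negative(self):
        alt = np.array([1, 1, 1] + [0] * 22)
        c = counts_from_arrays([alt], [np.full(25, 10)], pops=("A",))
        d = stats.tajimas_d(c, one_window(25), "A")
        assert d[0] < 0
        assert d[0] == pytest.approx(
            oracles.tajimas_d_textbook(alt, np.full(25, 10)), abs=1e-10)

    def test_intermediate_excess_positive(self):
        alt = np.array([5, 5, 5] + [0] * 22)
        c = counts_from_arrays([alt], [np.full(25, 10)], pops=("A",))
        d = stats.tajimas_d(c, one_window(25), "A")
        assert d[0] > 0

    def test_no_segregating_sites_missing(self):
        alt = np.zeros(25, dtype=int)
        c = counts_from_arrays([alt], [np.full(25, 10)], pops=("A",))
        assert np.isnan(stats.tajimas_d(c, one_window(25), "A")[0])


class TestFayWuH:
    def test_high_frequency_site_contribution(self):
        # single site i = 9, n = 10: pi = 0.2, theta_H = 1.8, H = -1.6
        c = counts_from_arrays([[9]], [[10]], pops=("A",))
        h = stats.fay_wu_h(c, one_window(1), "A")
        assert h[0] == pytest.approx(-1.6)

    def test_singletons_give_positive_h(self):
        alt = np.array([1, 1, 1, 1])
        c = counts_from_arrays([alt], [np.full(4, 10)], pops=("A",))
        assert stats.fay_wu_h(c, one_window(4), "A")[0] > 0

    def test_matches_textbook_oracle(self):
        rng = np.random.default_rng(2)
        alt = rng.integers(0, 11, 25)
        c = counts_from_arrays([alt], [np.full(25, 10)], pops=("A",))
        h = stats.fay_wu_h(c, one_window(25), "A")
        assert h[0] == pytest.approx(
            oracles.fay_wu_h_textbook(alt, np.full(25, 10)), abs=1e-10)


class TestFst:
    def test_fixed_difference_is_one(self):
        v = stats.per_snp_wc_fst([10], [10], [0], [10])
        assert v[0] == pytest.approx(1.0)

    def test_no_differentiation_nonpositive(self):
        rng = np.random.default_rng(3)
        alt = rng.integers(1, 10, 25)
        c = counts_from_arrays([alt, alt], [np.full(25, 10)] * 2)
        w = stats.fst(c, one_window(25), "A", "B")
        assert w[0] <= 0

    def test_matches_hand_algebra(self):
        v = stats.per_snp_wc_fst([6], [20], [14], [20])
        assert v[0] == pytest.approx(oracles.wc_fst_textbook(6, 20, 14, 20),
                                     abs=1e-12)

    def test_population_swap_invariance(self):
        rng = np.random.default_rng(4)
        a1, a2 = rng.integers(0, 11, 25), rng.integers(0, 11, 25)
        c = counts_from_arrays([a1, a2], [np.full(25, 10)] * 2)
        w = one_window(25)
        assert stats.fst(c, w, "A", "B")[0] == pytest.approx(
            stats.fst(c, w, "B", "A")[0])
        assert stats.afd_abs(c, w, "A", "B")[0] == pytest.approx(
            stats.afd_abs(c, w, "B", "A")[0])
        assert stats.dxy(c, w, "A", "B")[0][0] == pytest.approx(
            stats.dxy(c, w, "B", "A")[0][0])

    def test_ratio_of_sums_variant_close_to_mean_on_uniform_windows(self):
        rng = np.random.default_rng(9)
        a1, a2 = rng.integers(0, 11, 25), rng.integers(0, 11, 25)
        c = counts_from_arrays([a1, a2], [np.full(25, 10)] * 2)
        r = stats.fst(c, one_window(25), "A", "B", method="ratio")
        assert np.isfinite(r[0]) and -1 <= r[0] <= 1


class TestDxyAfd:
    def test_fixed_and_half(self):
        c = counts_from_arrays([[10, 5], [0, 5]], [[10, 10], [10, 10]])
        d, da = stats.dxy(c, np.array([[0], [1]]), "A", "B")
        assert d[0] == pytest.approx(1.0)
        assert d[1] == pytest.approx(0.5)

    def test_matches_pair_enumeration(self):
        rng = np.random.default_rng(5)
        a1, a2 = rng.integers(0, 9, 25), rng.integers(0, 13, 25)
        c = counts_from_arrays([a1, a2], [np.full(25, 8), np.full(25, 12)])
        d, _ = stats.dxy(c, one_window(25), "A", "B")
        expected = np.mean([oracles.dxy_bruteforce(i1, 8, i2, 12)
                            for i1, i2 in zip(a1, a2)])
        assert d[0] == pytest.approx(expected, abs=1e-12)

    def test_afd_examples_and_oracle(self):
        c = counts_from_arrays([[9, 5], [1, 5]], [[10, 10], [10, 10]])
        afd = stats.afd_abs(c, np.array([[0], [1]]), "A", "B")
        assert afd[0] == pytest.approx(0.8)
        assert afd[1] == pytest.approx(0.0)


class TestDdResiduals:
    def test_collinear_gives_zero(self):
        fst_vals = np.linspace(0.1, 0.5, 30)
        pi = 0.4 - 0.5 * fst_vals
        dd = stats.dd_residuals(pi, fst_vals)
        np.testing.assert_allclose(dd, 0, atol=1e-12)

    def test_normal_equations(self):
        rng = np.random.default_rng(6)
        fst_vals = rng.uniform(0, 0.5, 100)
        pi = 0.3 - 0.2 * fst_vals + rng.normal(0, 0.02, 100)
        dd = stats.dd_residuals(pi, fst_vals)
        assert abs(dd.sum()) < 1e-8
        assert abs((dd * fst_vals).sum()) < 1e-8

    def test_outlier_window_attains_minimum(self):
        fst_vals = np.linspace(0.1, 0.5, 30)
        pi = 0.4 - 0.5 * fst_vals
        pi[13] -= 0.2
        dd = stats.dd_residuals(pi, fst_vals)
        assert dd.argmin() == 13

    def test_constant_fst_degenerates_to_centred_pi(self):
        pi = np.linspace(0.1, 0.4, 20)
        dd = stats.dd_residuals(pi, np.full(20, 0.2))
        np.testing.assert_allclose(dd, pi - pi.mean(), atol=1e-12)


class TestFlk:
    def test_fixed_differences_scale_by_mean(self):
        c = counts_from_arrays([np.full(25, 10), np.zeros(25, int)],
                               [np.full(25, 10)] * 2)
        t = stats.flk(c, one_window(25), "A", "B", fst_bar=0.1)
        assert t[0] == pytest.approx(10.0)

    def test_linearity_in_fst(self):
        rng = np.random.default_rng(7)
        a1, a2 = rng.integers(0, 11, 25), rng.integers(0, 11, 25)
        c = counts_from_arrays([a1, a2], [np.full(25, 10)] * 2)
        t1 = stats.flk(c, one_window(25), "A", "B", fst_bar=0.2)
        t2 = stats.flk(c, one_window(25), "A", "B", fst_bar=0.1)
        assert t2[0] == pytest.approx(2 * t1[0])

    def test_nonpositive_mean_fst_is_error(self):
        c = counts_from_arrays([[1]], [[10]], pops=("A", "B"))
        with pytest.raises(ValueError, match="differentiation"):
            stats.flk(c, one_window(1), "A", "A", fst_bar=0.0)


class TestSfs2dClr:
    def _counts(self, rng, S, n=16):
        a1 = rng.integers(1, n, S)
        a2 = rng.integers(1, n, S)
        return counts_from_arrays([a1, a2], [np.full(S, n)] * 2)

    def test_identical_window_and_genome_spectrum_zero(self):
        rng = np.random.default_rng(8)
        c = self._counts(rng, 25)
        clr = stats.sfs2d_clr(c, one_window(25), "A", "B", np.arange(25))
        assert clr[0] == pytest.approx(0.0, abs=1e-9)

    def test_concentrated_window_scores_high_and_grows(self):
        rng = np.random.default_rng(9)
        S = 2000
        a1 = rng.integers(1, 8, S)
        a2 = rng.integers(1, 8, S)
        # plant two windows concentrated in a cell rare in the genome
        a1[:50] = 16
        a2[:50] = 1
        c = counts_from_arrays([a1, a2], [np.full(S, 16)] * 2)
        members = np.array([np.arange(25), np.arange(25, 50),
                            np.arange(50, 75)])
        clr = stats.sfs2d_clr(c, members, "A", "B", np.arange(S))
        assert clr[0] > clr[2] and clr[1] > clr[2]
        big = stats.sfs2d_clr(c, np.arange(50)[None, :], "A", "B",
                              np.arange(S))
        assert big[0] > clr[0]  # increasing in window size

    def test_too_few_projectable_sites_missing(self):
        c = counts_from_arrays([[1, 1], [1, 1]], [[4, 4], [4, 4]])
        clr = stats.sfs2d_clr(c, np.array([[0, 1]]), "A", "B", np.arange(2))
        assert np.isnan(clr[0])


class TestSweed:
    def test_alpha_zero_limit_recovers_background(self):
        rng = np.random.default_rng(10)
        S = 500
        alt = rng.integers(1, 16, S)
        c = counts_from_arrays([alt], [np.full(S, 16)], pops=("A",))
        pos = np.arange(S) * 100
        gp, clr = stats.sweed_clr(c, pos, np.arange(S), "A",
                                  alpha_grid=np.array([1e-12]))
        np.testing.assert_allclose(clr, 0, atol=1e-6)

    def test_swept_region_peaks_inside(self):
        rng = np.random.default_rng(11)
        S = 1000
        alt = rng.integers(1, 16, S)
        alt[450:550] = 16  # fixed derived: sweep-like
        c = counts_from_arrays([alt], [np.full(S, 16)], pops=("A",))
        pos = np.arange(S) * 100
        gp, clr = stats.sweed_clr(c, pos, np.arange(S), "A")
        peak = gp[np.argmax(clr)]
        assert 45000 <= peak <= 55000


class TestVarld:
    def test_identical_matrices_score_zero(self):
        rng = np.random.default_rng(12)
        dos = rng.integers(0, 3, (16, 25)).astype(np.int8)
        both = np.vstack([dos, dos])
        raw = stats.varld_raw(both, np.arange(16), np.arange(16, 32),
                              np.arange(25)[None, :])
        assert raw[0] == pytest.approx(0.0, abs=1e-10)

    def test_snp_order_permutation_invariance(self):
        rng = np.random.default_rng(13)
        dos = rng.integers(0, 3, (20, 25)).astype(np.int8)
        members = np.arange(25)[None, :]
        perm = rng.permutation(25)[None, :]
        r1 = stats.varld_raw(dos, np.arange(10), np.arange(10, 20), members)
        r2 = stats.varld_raw(dos, np.arange(10), np.arange(10, 20), perm)
        assert r1[0] == pytest.approx(r2[0], abs=1e-10)

    def test_eigenvalues_match_independent_decomposition(self):
        from scipy.linalg import eigh
        rng = np.random.default_rng(14)
        dos = rng.integers(0, 3, (10, 25)).astype(np.int8)
        R = stats._ld_correlation(dos.astype(float))
        ours = np.sort(np.linalg.eigvalsh(R))[::-1]
        theirs = np.sort(eigh(R, eigvals_only=True))[::-1]
        np.testing.assert_allclose(ours, theirs, atol=1e-8)


def test_metric_symmetry_under_population_swap():
    """FST, dXY, AFD and the VarLD score are invariant when the two
    populations of a contrast are exchanged."""
    rng = np.random.default_rng(15)
    a1, a2 = rng.integers(0, 17, 50), rng.integers(0, 17, 50)
    c = counts_from_arrays([a1, a2], [np.full(50, 16)] * 2)
    members = np.arange(50).reshape(2, 25)
    for fn in (stats.fst, stats.afd_abs):
        np.testing.assert_allclose(fn(c, members, "A", "B"),
                                   fn(c, members, "B", "A"), atol=1e-12)
    np.testing.assert_allclose(stats.dxy(c, members, "A", "B")[0],
                               stats.dxy(c, members, "B", "A")[0], atol=1e-12)
    dos = rng.integers(0, 3, (20, 50)).astype(np.int8)
    r_ab = stats.varld_raw(dos, np.arange(10), np.arange(10, 20), members)
    r_ba = stats.varld_raw(dos, np.arange(10, 20), np.arange(10), members)
    np.testing.assert_allclose(r_ab, r_ba, atol=1e-10)
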