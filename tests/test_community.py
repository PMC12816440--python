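import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from chromacomm.community import (discriminability_summary, gower_matrix,
                                  independent_swap, mntd, mpd, ses,
                                  swap_null_samples)


class TestGower:
    def test_identical_rows_zero(self):
        t = pd.DataFrame({"a": [1.0, 1.0], "b": ["x", "x"]}, index=["s1", "s2"])
        D = gower_matrix(t)
        assert D.loc["s1", "s2"] == 0.0

    def test_single_categorical_mismatch_is_one(self):
        t = pd.DataFrame({"b": ["x", "y"]}, index=["s1", "s2"])
        assert gower_matrix(t).loc["s1", "s2"] == 1.0

    def test_hand_computed_mixed_table(self):
        # numeric range 4: |1-3|/4=0.5, |1-5|/4=1, |3-5|/4=0.5
        # categorical: x/x match 0, x/y mismatch 1
        t = pd.DataFrame({"num": [1.0, 3.0, 5.0],
                          "cat": ["x", "x", "y"]},
                         index=["s1", "s2", "s3"])
        D = gower_matrix(t)
        assert D.loc["s1", "s2"] == pytest.approx((0.5 + 0.0) / 2)
        assert D.loc["s1", "s3"] == pytest.approx((1.0 + 1.0) / 2)
        assert D.loc["s2", "s3"] == pytest.approx((0.5 + 1.0) / 2)

    def test_missing_pairs_skipped(self):
        t = pd.DataFrame({"num": [1.0, np.nan, 5.0],
                          "cat": ["x", "x", "y"]},
                         index=["s1", "s2", "s3"])
        D = gower_matrix(t)
        # s1-s2 pair can only use the categorical trait
        assert D.loc["s1", "s2"] == 0.0

    def test_all_missing_species_rejected(self):
        t = pd.DataFrame({"num": [1.0, np.nan]}, index=["s1", "s2"])
        with pytest.raises(ValueError, match="missing"):
            gower_matrix(t)

    def test_bounds_symmetry_zero_diagonal(self):
        rng = np.random.default_rng(2)
        t = pd.DataFrame({
            "a": rng.normal(size=8), "b": rng.uniform(size=8),
            "c": rng.choice(list("xyz"), size=8)})
        D = gower_matrix(t).to_numpy()
        assert np.allclose(D, D.T)
        assert np.allclose(np.diag(D), 0.0)
        assert D.min() >= 0.0 and D.max() <= 1.0


class TestMetrics:
    def _random_D(self, n, seed):
        rng = np.random.default_rng(seed)
        D = rng.uniform(0.05, 1.0, size=(n, n))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0.0)
        return D

    def test_two_species_both_equal_pair_distance(self):
        D = self._random_D(4, 1)
        w = [1, 0, 1, 0]
        assert mpd(w, D) == pytest.approx(D[0, 2])
        assert mntd(w, D) == pytest.approx(D[0, 2])

    def test_constant_distances(self):
        D = np.full((5, 5), 0.7)
        np.fill_diagonal(D, 0.0)
        assert mpd([1] * 5, D) == pytest.approx(0.7)

    def test_mpd_matches_enumeration_oracle(self):
        D = self._random_D(6, 3)
        w = np.array([1, 1, 0, 1, 1, 1])
        present = np.flatnonzero(w)
        pairs = [D[i, j] for i, j in itertools.combinations(present, 2)]
        assert mpd(w, D) == pytest.approx(np.mean(pairs), abs=1e-12)

    def test_mntd_chain_hand_oracle(self):
        D = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 1.0], [2.0, 1.0, 0.0]])
        assert mntd([1, 1, 1], D) == pytest.approx(1.0)

    def test_mntd_never_exceeds_mpd(self):
        for seed in range(10):
            D = self._random_D(7, seed)
            w = np.ones(7)
            assert mntd(w, D) <= mpd(w, D) + 1e-12

    def test_species_reordering_invariance(self):
        D = self._random_D(6, 9)
        w = np.array([1, 0, 1, 1, 0, 1])
        perm = np.random.default_rng(0).permutation(6)
        assert mpd(w[perm], D[np.ix_(perm, perm)]) == pytest.approx(mpd(w, D))
        assert mntd(w[perm], D[np.ix_(perm, perm)]) == pytest.approx(mntd(w, D))

    def test_fewer_than_two_species_rejected(self):
        D = self._random_D(3, 4)
        with pytest.raises(ValueError):
            mpd([1, 0, 0], D)


class TestIndependentSwap:
    def test_no_checkerboard_unchanged(self):
        W = np.array([[1, 1], [1, 0]], dtype=np.int8)
        out = independent_swap(W, 1000, np.random.default_rng(0))
        np.testing.assert_array_equal(out, W)

    def test_margins_preserved_on_every_draw(self):
        rng = np.random.default_rng(1)
        W = (rng.random((12, 10)) < 0.4).astype(np.int8)
        for M in swap_null_samples(W, 20, rng, burn_in=500, thin=100):
            np.testing.assert_array_equal(M.sum(0), W.sum(0))
            np.testing.assert_array_equal(M.sum(1), W.sum(1))

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            independent_swap(np.array([[2, 0], [0, 1]]), 10,
                             np.random.default_rng(0))

    def test_swap_graph_sampled_uniformly(self):
        # enumerate all binary matrices sharing the margins of a 4x4 seed
        W0 = np.array([[1, 0, 1, 0],
                       [0, 1, 0, 1],
                       [1, 1, 0, 0],
                       [0, 0, 1, 1]], dtype=np.int8)
        rs, cs = W0.sum(1), W0.sum(0)
        states = []
        for bits in itertools.product([0, 1], repeat=16):
            M = np.array(bits, dtype=np.int8).reshape(4, 4)
            if (M.sum(1) == rs).all() and (M.sum(0) == cs).all():
                states.append(M.tobytes())
        counts = dict.fromkeys(states, 0)
        rng = np.random.default_rng(5)
        M = independent_swap(W0, 2000, rng)
        n_samples = 4000
        for _ in range(n_samples):
            M = independent_swap(M, 60, rng)
            counts[M.tobytes()] += 1
        observed = np.array(list(counts.values()))
        assert (observed > 0).all()  # every reachable state visited
        chi2 = ((observed - n_samples / len(states)) ** 2
                / (n_samples / len(states))).sum()
        p = stats.chi2.sf(chi2, len(states) - 1)
        assert p > 0.01


class TestSES:
    def test_constant_distance_degenerate(self):
        W = (np.random.default_rng(3).random((10, 6)) < 0.5).astype(np.int8)
        W[W.sum(1) < 2] = 1
        D = np.full((6, 6), 0.5)
        np.fill_diagonal(D, 0.0)
        res = ses("mpd", W, D, n_null=49, seed=1, burn_in=200, thin=50)
        assert res.table["degenerate"].all()

    def test_extreme_plot_gets_positive_z(self):
        rng = np.random.default_rng(4)
        n_sp = 12
        D = rng.uniform(0.0, 0.2, size=(n_sp, n_sp))
        D = (D + D.T) / 2
        D[0, 1] = D[1, 0] = 1.0  # the two most distant species
        np.fill_diagonal(D, 0.0)
        W = (rng.random((40, n_sp)) < 0.4).astype(np.int8)
        W[W.sum(1) < 2] = 1
        W[0] = 0
        W[0, [0, 1]] = 1  # plot holding exactly the distant pair
        res = ses("mpd", W, D, n_null=199, seed=2, burn_in=2000, thin=200)
        assert res.table["z"].iloc[0] > 0


class TestDiscriminability:
    def test_two_loci_above_threshold(self):
        mean_d, frac = discriminability_summary([[0.0, 0.0], [0.3, 0.0]], 0.2)
        assert mean_d == pytest.approx(0.3)
        assert frac == 1.0

    def test_identical_loci(self):
        mean_d, frac = discriminability_summary([[0.1, 0.1]] * 3, 0.2)
        assert mean_d == 0.0 and frac == 0.0

    def test_matches_brute_force_pair_loop(self):
        rng = np.random.default_rng(6)
        pts = rng.uniform(-1, 1, size=(5, 2))
        mean_d, frac = discriminability_summary(pts, 0.5)
        ds = [np.linalg.norm(pts[i] - pts[j])
              for i, j in itertools.combinations(range(5), 2)]
        assert mean_d == pytest.approx(np.mean(ds), abs=1e-12)
        assert frac == pytest.approx(np.mean([d >= 0.5 for d in ds]))
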