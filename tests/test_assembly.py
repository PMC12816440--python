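import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist

from chromacomm.assembly import (TraitAssemblyModel, cwm,
                                 fuzzy_weighted_composition,
                                 matrix_correlation, optimize_trait_subset,
                                 partial_matrix_correlation, remove_phylogeny,
                                 standardize, tcap_test, tdap_test,
                                 trait_selection)
from chromacomm.community import gower_matrix


class TestStandardize:
    def test_minmax_example(self):
        out = standardize(pd.DataFrame({"a": [2.0, 4.0, 6.0]}))
        np.testing.assert_allclose(out["a"], [0.0, 0.5, 1.0])

    def test_order_preserved(self):
        x = pd.DataFrame({"a": [0.3, 0.9, 0.1, 0.5]})
        out = standardize(x)
        assert list(out["a"].rank()) == list(x["a"].rank())

    def test_idempotent(self):
        x = pd.DataFrame({"a": [0.3, 0.9, 0.1]})
        once = standardize(x)
        np.testing.assert_allclose(standardize(once).to_numpy(),
                                   once.to_numpy())

    def test_zero_range_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="zero-range"):
            out = standardize(pd.DataFrame({"a": [1.0, 1.0], "b": [0.0, 2.0]}))
        assert list(out.columns) == ["b"]


class TestCWM:
    def test_single_species_plot(self):
        W = np.array([[1.0, 0.0]])
        B = np.array([[3.0, 7.0], [5.0, 9.0]])
        np.testing.assert_allclose(cwm(W, B), [[3.0, 7.0]])

    def test_equal_occurrence_mean(self):
        W = np.array([[1.0, 1.0]])
        B = np.array([[2.0], [6.0]])
        np.testing.assert_allclose(cwm(W, B), [[4.0]])

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(1)
        W = rng.integers(0, 3, size=(5, 6)).astype(float)
        W[W.sum(1) == 0, 0] = 1
        B = rng.normal(size=(6, 4))
        T = cwm(W, B)
        for p in range(5):
            for k in range(4):
                expected = sum(W[p, s] * B[s, k] for s in range(6)) / W[p].sum()
                assert T[p, k] == pytest.approx(expected, abs=1e-12)


class TestFuzzyComposition:
    def test_identity_similarity_row_normalized_w(self):
        # U = I means all species maximally distinct
        W = np.array([[1.0, 1.0, 0.0], [0.0, 1.0, 1.0]])
        G = 1.0 - np.eye(3)  # gower distance 1 everywhere off-diagonal
        X = fuzzy_weighted_composition(W, G)
        np.testing.assert_allclose(X, W / W.sum(1, keepdims=True))

    def test_identical_traits_uniform_rows(self):
        W = np.array([[1.0, 0.0, 1.0], [1.0, 1.0, 0.0]])
        G = np.zeros((3, 3))  # all species identical
        X = fuzzy_weighted_composition(W, G)
        np.testing.assert_allclose(X, 1.0 / 3.0)

    def test_hand_matrix_product(self):
        W = np.array([[1.0, 1.0, 0.0]])
        G = np.array([[0.0, 0.5, 1.0],
                      [0.5, 0.0, 0.5],
                      [1.0, 0.5, 0.0]])
        U = 1.0 - G
        U = U / U.sum(0, keepdims=True)
        X_hand = (W @ U)
        X_hand = X_hand / X_hand.sum()
        np.testing.assert_allclose(fuzzy_weighted_composition(W, G), X_hand,
                                   atol=1e-12)


class TestMatrixCorrelation:
    def test_self_correlation_one(self):
        M = np.random.default_rng(2).normal(size=(6, 3))
        assert matrix_correlation(M, M) == pytest.approx(1.0)

    def test_positive_scaling_invariance(self):
        M = np.random.default_rng(3).normal(size=(6, 3))
        assert matrix_correlation(M, 2.5 * M) == pytest.approx(1.0)

    def test_matches_brute_force_pearson(self):
        rng = np.random.default_rng(4)
        M1, M2 = rng.normal(size=(2, 6, 3))
        d1 = [np.linalg.norm(M1[i] - M1[j])
              for i, j in itertools.combinations(range(6), 2)]
        d2 = [np.linalg.norm(M2[i] - M2[j])
              for i, j in itertools.combinations(range(6), 2)]
        assert matrix_correlation(M1, M2) == pytest.approx(
            np.corrcoef(d1, d2)[0, 1], abs=1e-10)

    def test_partial_matches_textbook_formula(self):
        rng = np.random.default_rng(5)
        MX, ME, MT = rng.normal(size=(3, 7, 2))
        dx, de, dt = pdist(MX), pdist(ME), pdist(MT)
        r = np.corrcoef([dx, de, dt])
        expected = ((r[0, 1] - r[0, 2] * r[1, 2])
                    / np.sqrt((1 - r[0, 2] ** 2) * (1 - r[1, 2] ** 2)))
        assert partial_matrix_correlation(MX, ME, MT) == pytest.approx(
            expected, abs=1e-10)

    def test_partial_degenerate_flagged(self):
        # DX == DT gives r_XT = 1: the 0/0 guard must return nan
        M = np.random.default_rng(6).normal(size=(6, 2))
        E = np.random.default_rng(7).normal(size=(6, 2))
        assert np.isnan(partial_matrix_correlation(M, E, M))


class TestPermutationTests:
    def _data(self, seed=0, n_plots=25, n_sp=15):
        rng = np.random.default_rng(seed)
        W = (rng.random((n_plots, n_sp)) < 0.4).astype(float)
        W[W.sum(1) < 2] = 1
        B = rng.normal(size=(n_sp, 3))
        E = rng.normal(size=(n_plots, 2))
        return W, B, E

    def test_zero_permutations_rejected(self):
        W, B, E = self._data()
        with pytest.raises(ValueError, match="permutations"):
            tcap_test(W, B, E, n_perm=0)
        with pytest.raises(ValueError, match="permutations"):
            tdap_test(W, B, E, n_perm=0)

    def test_tcap_detects_convergent_generator(self):
        # environmental filtering planted by the convergent generator mode
        from chromacomm.synthetic import SimConfig, gen_community
        ds = gen_community(SimConfig.reduced(seed=1,
                                             assembly_mode="convergent"))
        W = ds.W.to_numpy(float)
        keep = W.sum(1) >= 2
        latent = [c for c in ds.traits.columns if c.startswith("trait")]
        B = standardize(ds.traits[latent]).to_numpy()
        E = standardize(pd.get_dummies(ds.env_matrix(), dtype=float)
                        ).loc[keep].to_numpy()
        rho, p = tcap_test(W[keep], B, E, n_perm=199, seed=2)
        assert p <= 0.05

    def test_tcap_null_p_roughly_uniform(self):
        # E independent of traits: p-values should not pile up near 0
        ps = []
        for i in range(40):
            W, B, E = self._data(seed=100 + i)
            _, p = tcap_test(W, B, E, n_perm=99, seed=i)
            ps.append(p)
        from scipy import stats
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_tdap_constant_trait_degenerate(self):
        W, _, E = self._data()
        B = np.ones((15, 1))
        rho, p = tdap_test(W, B, E, n_perm=19, seed=0)
        assert np.isnan(rho) and np.isnan(p)


class TestRemovePhylogeny:
    def _phylo_distance(self, n, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(n, 3))
        from scipy.spatial.distance import squareform
        return squareform(pdist(pts))

    def test_residuals_orthogonal_to_retained_axes(self):
        P = self._phylo_distance(12, 1)
        rng = np.random.default_rng(2)
        B = pd.DataFrame(rng.normal(size=(12, 3)), columns=list("abc"))
        resid = remove_phylogeny(B, P, k_axes=3)
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.ordination import pcoa
        axes = pcoa(DistanceMatrix(P, ids=[str(i) for i in range(12)]),
                    method="eigh").samples.to_numpy()[:, :3]
        for col in resid.columns:
            dots = axes.T @ resid[col].to_numpy()
            assert np.max(np.abs(dots)) < 1e-8

    def test_trait_in_phylo_subspace_dropped(self):
        P = self._phylo_distance(10, 3)
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.ordination import pcoa
        ax1 = pcoa(DistanceMatrix(P, ids=[str(i) for i in range(10)]),
                   method="eigh").samples.to_numpy()[:, 0]
        B = pd.DataFrame({"phylo_trait": ax1,
                          "free": np.random.default_rng(4).normal(size=10)})
        with pytest.warns(UserWarning, match="phylogeny"):
            resid = remove_phylogeny(B, P, k_axes=2)
        assert "phylo_trait" not in resid.columns

    def test_k_exceeding_positive_eigenvalues_rejected(self):
        P = self._phylo_distance(6, 5)
        B = pd.DataFrame({"a": np.arange(6.0)})
        with pytest.raises(ValueError, match="exceeds"):
            remove_phylogeny(B, P, k_axes=6)


class TestTraitSelection:
    def test_exact_linear_cwm(self):
        n_plots = 12
        elev = np.linspace(800, 1400, n_plots)
        W = np.eye(n_plots)  # one species per plot
        B = pd.DataFrame({"t": 2.0 * elev})  # CWM == 2*elevation exactly
        tab = trait_selection(W, B, elev, selected_subset=["t"])
        row = tab.iloc[0]
        assert row["R2"] == pytest.approx(1.0)
        assert row["Direction"] == "+"
        assert bool(row["Selected"])

    def test_schema_columns(self):
        W = np.eye(5)
        B = pd.DataFrame({"t": [1.0, 2.0, 1.5, 3.0, 2.5]})
        tab = trait_selection(W, B, np.arange(5.0))
        assert list(tab.columns) == ["Variable", "P", "R2", "Direction",
                                     "Selected"]

    def test_subset_search_recovers_informative_trait(self):
        rng = np.random.default_rng(7)
        n_sp, n_plots = 15, 20
        grad = np.linspace(0, 1, n_plots)
        B = pd.DataFrame({"signal": np.linspace(0, 1, n_sp),
                          "noise": rng.normal(size=n_sp)})
        W = np.zeros((n_plots, n_sp))
        for p in range(n_plots):
            w = np.exp(-((B["signal"].to_numpy() - grad[p]) ** 2) / 0.02) + 1e-9
            W[p, rng.choice(n_sp, 4, replace=False, p=w / w.sum())] = 1
        subset, score = optimize_trait_subset(W, B, grad[:, None])
        assert "signal" in subset


class TestModelAPI:
    def test_fit_returns_seven_named_tests(self):
        rng = np.random.default_rng(9)
        n_sp, n_plots = 12, 16
        species = [f"s{i}" for i in range(n_sp)]
        W = pd.DataFrame((rng.random((n_plots, n_sp)) < 0.5).astype(int),
                         columns=species)
        W.loc[W.sum(1) < 2, species[0]] = 1
        B = pd.DataFrame(rng.normal(size=(n_sp, 2)), index=species,
                         columns=["t1", "t2"])
        E = pd.DataFrame({"elevation": rng.uniform(800, 1400, n_plots),
                          "vegetation": rng.choice(["RO", "SA"], n_plots)})
        pts = rng.normal(size=(n_sp, 3))
        from scipy.spatial.distance import squareform
        P = pd.DataFrame(squareform(pdist(pts)), index=species, columns=species)
        res = TraitAssemblyModel(W=W, B=B, E=E, P=P).fit(n_perm=39, seed=0)
        assert len(res.table) == 7
        assert res.table["test"].str.startswith("(").all()
        ps = res.pvalues().dropna()
        assert ((ps > 0) & (ps <= 1)).all()
        assert "Trait assembly" in res.summary()

    def test_species_mismatch_rejected(self):
        W = pd.DataFrame(np.ones((3, 2), int), columns=["a", "b"])
        B = pd.DataFrame(np.ones((2, 1)), index=["b", "a"], columns=["t"])
        E = pd.DataFrame({"elevation": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="same species"):
            TraitAssemblyModel(W=W, B=B, E=E)
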