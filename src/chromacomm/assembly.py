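"""Trait-convergence / trait-divergence assembly analysis and the
trait-selection regressions.

The framework relates four matrices — W (plots x species occurrences),
B (species x standardized traits), E (plots x standardized environment)
and P (species x species phylogenetic distances) — through matrix
correlations between plot-pairwise Euclidean distances:

* trait convergence (TCAP): rho(TE), T = community-weighted trait means;
* trait divergence (TDAP): rho(XE.T), the partial correlation between the
  trait-similarity-weighted composition X and E, controlling T;
* phylogenetic structure: the same correlations computed on the
  phylogenetically weighted composition X_P;
* "removing phylogeny": TCAP/TDAP on trait residuals from the principal
  coordinates of P.

Significance comes from permutation nulls — shuffling species rows of B
(tests 1, 2, 6, 7) or tips of P (tests 3-5) — each null breaking exactly
the linkage under test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from .community import gower_matrix

N_PERM_DEFAULT = 1000

TEST_NAMES = (
    "(1) Trait convergence: assembly patterns",
    "(2) Trait divergence: assembly patterns",
    "(3) Phylogenetic structure: environment",
    "(4) Phylogenetic structure: trait convergence",
    "(5) Phylogenetic structure: trait divergence",
    "(6) Removing phylogeny: trait convergence",
    "(7) Removing phylogeny: trait divergence",
)


# ---------------------------------------------------------------- primitives

def standardize(df: pd.DataFrame) -> pd.DataFrame:
    """Per-column min-max standardization to [0, 1]; zero-range columns are
    dropped with a warning (they carry no gradient information)."""
    out = {}
    for col in df.columns:
        x = df[col].to_numpy(float)
        lo, hi = np.nanmin(x), np.nanmax(x)
        if hi - lo == 0:
            warnings.warn(f"dropping zero-range column {col!r}")
            continue
        out[col] = (x - lo) / (hi - lo)
    if not out:
        raise ValueError("no columns with nonzero range")
    return pd.DataFrame(out, index=df.index)


def cwm(W: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Community-weighted means T_pk = sum_s w_ps B_sk / sum_s w_ps."""
    W = np.asarray(W, dtype=float)
    B = np.asarray(B, dtype=float)
    tot = W.sum(axis=1, keepdims=True)
    if np.any(tot == 0):
        raise ValueError("plot with no species: cannot form CWM")
    return (W @ B) / tot


def fuzzy_weighted_composition(W: np.ndarray, B_gower: np.ndarray) -> np.ndarray:
    """Trait-similarity-weighted composition X.

    U = 1 - Gower distance among species, columns rescaled to sum 1;
    X = W.U with rows rescaled to sum 1.
    """
    U = 1.0 - np.asarray(B_gower, dtype=float)
    colsum = U.sum(axis=0, keepdims=True)
    if np.any(colsum <= 0):
        raise ValueError("species with undefined similarity (zero column sum)")
    U = U / colsum
    X = np.asarray(W, dtype=float) @ U
    rowsum = X.sum(axis=1, keepdims=True)
    if np.any(rowsum <= 0):
        raise ValueError("plot with zero similarity-weighted composition")
    return X / rowsum


def matrix_correlation(M1: np.ndarray, M2: np.ndarray) -> float:
    """Pearson correlation between plot-pairwise Euclidean distances of the
    rows of two matrices (strict lower triangles)."""
    d1 = pdist(np.asarray(M1, dtype=float))
    d2 = pdist(np.asarray(M2, dtype=float))
    return _pearson(d1, d2)


def _pearson(d1: np.ndarray, d2: np.ndarray) -> float:
    s1, s2 = d1.std(), d2.std()
    if s1 == 0 or s2 == 0:
        return np.nan
    return float(np.corrcoef(d1, d2)[0, 1])


def partial_matrix_correlation(MX, ME, MT) -> float:
    """Partial Pearson rho(XE.T) on vectorized distance triangles."""
    dx, de, dt = (pdist(np.asarray(m, dtype=float)) for m in (MX, ME, MT))
    return _partial_from_vectors(dx, de, dt)


def _partial_from_vectors(dx, de, dt) -> float:
    r_xe = _pearson(dx, de)
    r_xt = _pearson(dx, dt)
    r_et = _pearson(de, dt)
    if any(np.isnan(v) for v in (r_xe, r_xt, r_et)):
        return np.nan
    denom = (1 - r_xt ** 2) * (1 - r_et ** 2)
    if denom <= 0:
        return np.nan
    return (r_xe - r_xt * r_et) / np.sqrt(denom)


# ---------------------------------------------------------------- tests

def _perm_p(obs: float, null: np.ndarray, n_perm: int) -> float:
    """One-sided (>=) permutation p with the +1 correction."""
    ok = np.isfinite(null)
    return float((np.sum(null[ok] >= obs) + 1) / (n_perm + 1))


def tcap_test(W, B, E, n_perm: int = N_PERM_DEFAULT, seed=None):
    """Trait-convergence test: observed rho(TE) against the null obtained by
    permuting species rows of B. Returns (rho, p)."""
    if n_perm <= 0:
        raise ValueError("permutations required (n_perm >= 1)")
    W = np.asarray(W, dtype=float)
    B = np.asarray(B, dtype=float)
    dE = pdist(np.asarray(E, dtype=float))
    Wn = W / W.sum(axis=1, keepdims=True)
    rho = _pearson(pdist(Wn @ B), dE)
    if np.isnan(rho):
        return np.nan, np.nan
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(B.shape[0])
        null[b] = _pearson(pdist(Wn @ B[perm]), dE)
    return rho, _perm_p(rho, null, n_perm)


def tdap_test(W, B, E, n_perm: int = N_PERM_DEFAULT, seed=None,
              B_frame: pd.DataFrame | None = None):
    """Trait-divergence test: observed partial rho(XE.T) against the
    species-row permutation null (U and T rebuilt per draw). Returns (rho, p).

    ``B_frame`` (mixed-type DataFrame) is used for the Gower similarities if
    given; otherwise Gower is computed on the numeric array B.
    """
    if n_perm <= 0:
        raise ValueError("permutations required (n_perm >= 1)")
    W = np.asarray(W, dtype=float)
    B = np.asarray(B, dtype=float)
    frame = B_frame if B_frame is not None else pd.DataFrame(B)
    try:
        G = gower_matrix(frame).to_numpy()
    except ValueError:
        return np.nan, np.nan  # degenerate trait table (e.g. all constant)
    dE = pdist(np.asarray(E, dtype=float))
    Wn = W / W.sum(axis=1, keepdims=True)

    def stat(perm):
        Gp = G[np.ix_(perm, perm)]
        X = fuzzy_weighted_composition(W, Gp)
        T = Wn @ B[perm]
        return _partial_from_vectors(pdist(X), dE, pdist(T))

    ident = np.arange(B.shape[0])
    rho = stat(ident)
    if np.isnan(rho):
        return np.nan, np.nan
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        null[b] = stat(rng.permutation(B.shape[0]))
    return rho, _perm_p(rho, null, n_perm)


def phylo_weighted_composition(W: np.ndarray, P: np.ndarray) -> np.ndarray:
    """X_P = W.Q with Q = column-normalized (1 - P / max(P)), rows of X_P
    rescaled to sum 1."""
    P = np.asarray(P, dtype=float)
    mx = P.max()
    if mx <= 0:
        raise ValueError("degenerate phylogenetic distance matrix")
    Q = 1.0 - P / mx
    colsum = Q.sum(axis=0, keepdims=True)
    if np.any(colsum <= 0):
        raise ValueError("zero column sum in phylogenetic weights")
    Q = Q / colsum
    X = np.asarray(W, dtype=float) @ Q
    return X / X.sum(axis=1, keepdims=True)


def phylo_structure_tests(W, B, E, P, n_perm: int = N_PERM_DEFAULT, seed=None,
                          B_frame: pd.DataFrame | None = None):
    """Tests 3-5: correlations of the phylogenetically weighted composition
    with E, T (convergence carrier) and X (divergence carrier), with a
    tip-shuffle null on P. Returns list of (rho, p)."""
    if n_perm <= 0:
        raise ValueError("permutations required (n_perm >= 1)")
    W = np.asarray(W, dtype=float)
    B = np.asarray(B, dtype=float)
    P = np.asarray(P, dtype=float)
    frame = B_frame if B_frame is not None else pd.DataFrame(B)
    G = gower_matrix(frame).to_numpy()
    Wn = W / W.sum(axis=1, keepdims=True)
    dE = pdist(np.asarray(E, dtype=float))
    dT = pdist(Wn @ B)
    dX = pdist(fuzzy_weighted_composition(W, G))
    targets = (dE, dT, dX)

    def stats_for(perm):
        Pp = P[np.ix_(perm, perm)]
        dXP = pdist(phylo_weighted_composition(W, Pp))
        return [_pearson(dXP, t) for t in targets]

    ident = np.arange(P.shape[0])
    obs = stats_for(ident)
    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, 3))
    for b in range(n_perm):
        null[b] = stats_for(rng.permutation(P.shape[0]))
    out = []
    for j in range(3):
        if np.isnan(obs[j]):
            out.append((np.nan, np.nan))
        else:
            out.append((obs[j], _perm_p(obs[j], null[:, j], n_perm)))
    return out


def remove_phylogeny(B: pd.DataFrame, P: np.ndarray, k_axes: int | None = None,
                     trace_fraction: float = 0.95) -> pd.DataFrame:
    """Residualize each trait column on the principal-coordinate axes of P.

    Axes are the top PCoA eigenvectors (by eigenvalue) explaining
    ``trace_fraction`` of the positive-eigenvalue trace, or exactly
    ``k_axes`` if given. Columns whose residual collapses to ~0 (traits
    lying in the phylogenetic subspace) are dropped with a warning.
    """
    from skbio.stats.distance import DistanceMatrix
    from skbio.stats.ordination import pcoa

    P = np.asarray(P, dtype=float)
    ids = [str(i) for i in range(P.shape[0])]
    ord_res = pcoa(DistanceMatrix(P, ids=ids), method="eigh",
                   number_of_dimensions=P.shape[0])
    eig = ord_res.eigvals.to_numpy()
    pos = eig > 1e-10
    n_pos = int(pos.sum())
    if k_axes is not None:
        if k_axes > n_pos:
            raise ValueError(f"k_axes={k_axes} exceeds {n_pos} positive eigenvalues")
        k = k_axes
    else:
        cum = np.cumsum(eig[pos]) / eig[pos].sum()
        k = int(np.searchsorted(cum, trace_fraction) + 1)
    axes = ord_res.samples.to_numpy()[:, :k]
    design = np.column_stack([np.ones(P.shape[0]), axes])
    out = {}
    for col in B.columns:
        y = B[col].to_numpy(float)
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ beta
        if np.max(np.abs(resid)) < 1e-10:
            warnings.warn(f"trait {col!r} fully explained by phylogeny; dropped")
            continue
        out[col] = resid
    if not out:
        raise ValueError("all traits lie in the phylogenetic subspace")
    return pd.DataFrame(out, index=B.index)


# ---------------------------------------------------------------- selection

def optimize_trait_subset(W, B: pd.DataFrame, E, criterion: str = "tcap",
                          max_exhaustive: int = 12):
    """Trait subset maximizing the observed assembly statistic.

    Exhaustive over all nonempty subsets when B has <= ``max_exhaustive``
    columns, greedy forward otherwise; ties broken by fewer traits.
    """
    cols = list(B.columns)
    W = np.asarray(W, dtype=float)
    E = np.asarray(E, dtype=float)
    dE = pdist(E)
    Wn = W / W.sum(axis=1, keepdims=True)

    def score(subset):
        Bs = B[list(subset)].to_numpy(float)
        if criterion == "tcap":
            return _pearson(pdist(Wn @ Bs), dE)
        G = gower_matrix(B[list(subset)]).to_numpy()
        X = fuzzy_weighted_composition(W, G)
        return _partial_from_vectors(pdist(X), dE, pdist(Wn @ Bs))

    best, best_score = None, -np.inf
    if len(cols) <= max_exhaustive:
        for k in range(1, len(cols) + 1):
            for subset in combinations(cols, k):
                s = score(subset)
                if np.isfinite(s) and s > best_score + 1e-12:
                    best, best_score = list(subset), s
    else:
        remaining = cols[:]
        current: list = []
        current_score = -np.inf
        improved = True
        while improved and remaining:
            improved = False
            cand_best, cand_score = None, current_score
            for c in remaining:
                s = score(current + [c])
                if np.isfinite(s) and s > cand_score + 1e-12:
                    cand_best, cand_score = c, s
            if cand_best is not None:
                current.append(cand_best)
                remaining.remove(cand_best)
                current_score = cand_score
                improved = True
        best, best_score = current, current_score
    if best is None:
        raise ValueError("no trait subset yields a defined statistic")
    return best, float(best_score)


def trait_selection(W, B: pd.DataFrame, elevation, alpha: float = 0.05,
                    selected_subset=None) -> pd.DataFrame:
    """Per-trait OLS of the CWM on plot elevation.

    Returns a table with columns Variable, P, R2, Direction ("+"/"-" when
    p < alpha, else "NA"), and Selected (trait both in the assembly-
    optimized subset and regression-significant).
    """
    from .models import ols

    W = np.asarray(W, dtype=float)
    T = cwm(W, B.to_numpy(float))
    elev = np.asarray(elevation, dtype=float)
    rows = []
    for j, col in enumerate(B.columns):
        y = T[:, j]
        if np.ptp(y) == 0:
            rows.append({"Variable": col, "P": np.nan, "R2": np.nan,
                         "Direction": "NA", "Selected": False})
            continue
        fit = ols(y, elev)
        p = fit.pvalues[1]
        slope = fit.params[1]
        direction = ("+" if slope > 0 else "-") if p < alpha else "NA"
        sel = (selected_subset is not None and col in selected_subset
               and p < alpha)
        rows.append({"Variable": col, "P": p, "R2": fit.rsquared,
                     "Direction": direction, "Selected": bool(sel)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------- model API

@dataclass
class TraitAssemblyModel:
    """Convergence/divergence assembly analysis, statsmodels-style.

    Parameters
    ----------
    W : DataFrame
        Plots x species occurrences (0/1 or counts); species order must
        match ``B``'s and ``P``'s.
    B : DataFrame
        Species x traits. Numeric columns are min-max standardized;
        categorical columns participate in the Gower similarities only.
    E : DataFrame
        Plots x environment. Non-numeric columns (e.g. vegetation type) are
        expanded to 0/1 indicators; all columns min-max standardized.
    P : DataFrame, optional
        Species x species phylogenetic distances (enables tests 3-7).
    """

    W: pd.DataFrame
    B: pd.DataFrame
    E: pd.DataFrame
    P: pd.DataFrame | None = None
    B_std: pd.DataFrame = field(init=False)
    E_std: pd.DataFrame = field(init=False)

    def __post_init__(self):
        if list(self.W.columns) != list(self.B.index):
            raise ValueError("W columns and B rows must list the same species in order")
        if self.P is not None and list(self.P.index) != list(self.B.index):
            raise ValueError("P must be indexed by the same species as B")
        if len(self.E) != len(self.W):
            raise ValueError("E must have one row per plot of W")
        drop = self.E.isna().any(axis=1) | (self.W.sum(axis=1) == 0)
        if drop.any():
            self.W = self.W.loc[~drop.to_numpy()]
            self.E = self.E.loc[~drop.to_numpy()]
        numB = self.B.select_dtypes(include=[np.number])
        if numB.shape[1] == 0:
            raise ValueError("B needs at least one numeric trait")
        self.B_std = standardize(numB)
        E = pd.get_dummies(self.E, dtype=float)
        self.E_std = standardize(E)

    def fit(self, n_perm: int = N_PERM_DEFAULT, seed=None) -> "AssemblyResults":
        rng = np.random.default_rng(seed)
        seeds = rng.integers(0, 2**31 - 1, size=5)
        W = self.W.to_numpy(float)
        B = self.B_std.to_numpy(float)
        E = self.E_std.to_numpy(float)
        rows = {}
        rows[TEST_NAMES[0]] = tcap_test(W, B, E, n_perm, seed=int(seeds[0]))
        rows[TEST_NAMES[1]] = tdap_test(W, B, E, n_perm, seed=int(seeds[1]),
                                        B_frame=self.B_std)
        if self.P is not None:
            phylo = phylo_structure_tests(W, B, E, self.P.to_numpy(float),
                                          n_perm, seed=int(seeds[2]),
                                          B_frame=self.B_std)
            for name, rp in zip(TEST_NAMES[2:5], phylo):
                rows[name] = rp
            B_res = remove_phylogeny(self.B_std, self.P.to_numpy(float))
            Br = B_res.to_numpy(float)
            rows[TEST_NAMES[5]] = tcap_test(W, Br, E, n_perm, seed=int(seeds[3]))
            rows[TEST_NAMES[6]] = tdap_test(W, Br, E, n_perm, seed=int(seeds[4]),
                                            B_frame=B_res)
        else:
            for name in TEST_NAMES[2:]:
                rows[name] = (np.nan, np.nan)
        table = pd.DataFrame(
            [{"test": k, "rho": v[0], "p": v[1]} for k, v in rows.items()]
        )
        return AssemblyResults(model=self, table=table, n_perm=n_perm)


@dataclass
class AssemblyResults:
    model: TraitAssemblyModel
    table: pd.DataFrame  # columns: test, rho, p
    n_perm: int

    def pvalues(self) -> pd.Series:
        return self.table.set_index("test")["p"]

    def trait_selection(self, elevation=None, alpha: float = 0.05) -> pd.DataFrame:
        if elevation is None:
            if "elevation" not in self.model.E.columns:
                raise ValueError("pass elevation or include an 'elevation' column in E")
            elevation = self.model.E["elevation"].to_numpy(float)
        subset, _ = optimize_trait_subset(self.model.W.to_numpy(float),
                                          self.model.B_std,
                                          self.model.E_std.to_numpy(float))
        return trait_selection(self.model.W.to_numpy(float), self.model.B_std,
                               elevation, alpha=alpha, selected_subset=subset)

    def summary(self) -> str:
        lines = [f"Trait assembly permutation tests ({self.n_perm} randomizations, "
                 f"{len(self.model.W)} plots, {self.model.B_std.shape[1]} traits)"]
        for _, row in self.table.iterrows():
            star = " *" if np.isfinite(row["p"]) and row["p"] < 0.05 else ""
            rho = f"{row['rho']:.3f}" if np.isfinite(row["rho"]) else "   NA"
            p = f"{row['p']:.3f}" if np.isfinite(row["p"]) else "NA"
            lines.append(f"  {row['test']:<50s} rho = {rho}  p = {p}{star}")
        return "\n".join(lines)
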