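"""Plot-level color diversity: Gower distances, MPD/MNTD, SES null models,
and color-loci discriminability summaries.

The null model is the independent swap: repeated 2x2 checkerboard swaps of
a binary plot x species matrix, which preserve every plot's richness (row
sums) and every species' occurrence frequency (column sums) exactly.
Standardized effect sizes are z = (obs - mean_null) / sd_null with a
two-sided empirical p carrying the +1 correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: spec'd defaults for the swap chain
SWAP_BURN_IN = 10_000
SWAP_THIN = 1_000
N_NULL_DEFAULT = 999


# ---------------------------------------------------------------- Gower

def gower_matrix(traits: pd.DataFrame, columns=None) -> pd.DataFrame:
    """Mixed-type Gower distance among species (rows of ``traits``).

    Numeric columns contribute |dx| / range; categorical columns contribute
    a 0/1 mismatch; each pair averages over the traits observed in both
    species. Distances lie in [0, 1], are symmetric, and are 0 on the
    diagonal.
    """
    sub = traits[list(columns)] if columns is not None else traits
    if sub.shape[1] == 0:
        raise ValueError("no usable trait columns")
    n = len(sub)
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    used_any = np.zeros(n, dtype=bool)
    for col in sub.columns:
        s = sub[col]
        if pd.api.types.is_numeric_dtype(s):
            x = s.to_numpy(float)
            ok = np.isfinite(x)
            rng = np.nanmax(x[ok]) - np.nanmin(x[ok]) if ok.any() else 0.0
            if rng == 0 or not ok.any():
                continue  # constant or empty trait carries no information
            d = np.abs(x[:, None] - x[None, :]) / rng
            valid = ok[:, None] & ok[None, :]
        else:
            x = s.astype("object").to_numpy()
            ok = pd.notna(s).to_numpy()
            d = (x[:, None] != x[None, :]).astype(float)
            valid = ok[:, None] & ok[None, :]
        num += np.where(valid, np.nan_to_num(d), 0.0)
        den += valid
        used_any |= ok
    if not used_any.all():
        bad = sub.index[~used_any].tolist()
        raise ValueError(f"species with all traits missing: {bad}")
    with np.errstate(invalid="ignore"):
        D = np.where(den > 0, num / den, np.nan)
    np.fill_diagonal(D, 0.0)
    return pd.DataFrame(D, index=sub.index, columns=sub.index)


# ---------------------------------------------------------------- metrics

def mpd(presence, D) -> float:
    """Mean pairwise distance among the species present (presence/absence)."""
    w = np.asarray(presence, dtype=bool)
    k = int(w.sum())
    if k < 2:
        raise ValueError("mpd needs at least two species present")
    sub = np.asarray(D)[np.ix_(w, w)]
    return float(sub[np.triu_indices(k, 1)].mean())


def mntd(presence, D) -> float:
    """Mean nearest-neighbor distance among the species present."""
    w = np.asarray(presence, dtype=bool)
    k = int(w.sum())
    if k < 2:
        raise ValueError("mntd needs at least two species present")
    sub = np.asarray(D)[np.ix_(w, w)].copy()
    np.fill_diagonal(sub, np.inf)
    return float(sub.min(axis=1).mean())


def _mpd_all_plots(W: np.ndarray, D: np.ndarray) -> np.ndarray:
    """Vectorized MPD for every row of binary W (nan where richness < 2)."""
    Wf = W.astype(float)
    k = Wf.sum(axis=1)
    tot = np.einsum("ps,st,pt->p", Wf, D, Wf)  # includes both triangles
    with np.errstate(invalid="ignore", divide="ignore"):
        out = tot / (k * (k - 1))
    out[k < 2] = np.nan
    return out


def _mntd_all_plots(W: np.ndarray, D: np.ndarray) -> np.ndarray:
    n_plots = W.shape[0]
    out = np.full(n_plots, np.nan)
    Dinf = D.copy()
    np.fill_diagonal(Dinf, np.inf)
    for p in range(n_plots):
        w = W[p].astype(bool)
        if w.sum() < 2:
            continue
        sub = Dinf[np.ix_(w, w)]
        out[p] = sub.min(axis=1).mean()
    return out


# ---------------------------------------------------------------- null model

def independent_swap(W: np.ndarray, n_swaps: int, rng) -> np.ndarray:
    """Randomize a binary matrix by checkerboard swaps (in a copy).

    ``n_swaps`` counts attempted 2x2 submatrix picks; a pick is swapped only
    when it forms a checkerboard ([[1,0],[0,1]] or [[0,1],[1,0]]), so row
    and column sums are preserved exactly on every draw.
    """
    M = np.asarray(W)
    if not np.isin(M, (0, 1)).all():
        raise ValueError("independent swap requires a binary matrix")
    M = M.astype(np.int8).copy()
    n, m = M.shape
    if n < 2 or m < 2 or n_swaps <= 0:
        return M
    rows = rng.integers(0, n, size=(n_swaps, 2))
    cols = rng.integers(0, m, size=(n_swaps, 2))
    for t in range(n_swaps):
        r1, r2 = rows[t]
        c1, c2 = cols[t]
        if r1 == r2 or c1 == c2:
            continue
        a = M[r1, c1]
        if a == M[r2, c2] and M[r1, c2] == M[r2, c1] and a != M[r1, c2]:
            M[r1, c1] = M[r2, c2] = 1 - a
            M[r1, c2] = M[r2, c1] = a
    return M


def swap_null_samples(W: np.ndarray, n_samples: int, rng,
                      burn_in: int = SWAP_BURN_IN, thin: int = SWAP_THIN):
    """Yield ``n_samples`` draws from the independent-swap chain."""
    M = independent_swap(W, burn_in, rng)
    for _ in range(n_samples):
        M = independent_swap(M, thin, rng)
        yield M


# ---------------------------------------------------------------- SES

@dataclass
class SESResult:
    """Per-plot standardized effect sizes for one metric."""

    metric: str
    table: pd.DataFrame  # columns: observed, null_mean, null_sd, z, p, degenerate
    n_null: int

    @property
    def z(self) -> pd.Series:
        return self.table["z"]

    def summary(self) -> str:
        ok = self.table.dropna(subset=["z"])
        return (f"SES {self.metric}: {len(ok)}/{len(self.table)} plots, "
                f"mean z = {ok['z'].mean():.3f}, sd z = {ok['z'].std(ddof=1):.3f}, "
                f"{int((ok['p'] < 0.05).sum())} plots with p < 0.05 "
                f"({self.n_null} randomizations)")


def ses(metric: str, W, D, n_null: int = N_NULL_DEFAULT, seed=None,
        burn_in: int | None = None, thin: int | None = None,
        plot_index=None) -> SESResult:
    """SES of MPD or MNTD per plot against the independent-swap null.

    ``burn_in`` and ``thin`` count swap attempts; by default they scale with
    the number of plots (minima 10,000 and 1,000) so the chain mixes
    comparably on matrices of any size.
    """
    W = np.asarray(W)
    D = np.asarray(D)
    if burn_in is None:
        burn_in = max(SWAP_BURN_IN, 50 * W.shape[0])
    if thin is None:
        thin = max(SWAP_THIN, 5 * W.shape[0])
    fn = {"mpd": _mpd_all_plots, "mntd": _mntd_all_plots}.get(metric)
    if fn is None:
        raise ValueError("metric must be 'mpd' or 'mntd'")
    rng = np.random.default_rng(seed)
    obs = fn(W, D)
    null = np.empty((n_null, W.shape[0]))
    for i, M in enumerate(swap_null_samples(W, n_null, rng, burn_in, thin)):
        null[i] = fn(M, D)
    mean = np.nanmean(null, axis=0)
    sd = np.nanstd(null, axis=0, ddof=1)
    degenerate = (sd == 0) | ~np.isfinite(sd) | ~np.isfinite(obs)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (obs - mean) / sd
    z[degenerate] = np.nan
    # two-sided empirical p with the +1 correction
    n_ge = np.nansum(null >= obs[None, :], axis=0)
    n_le = np.nansum(null <= obs[None, :], axis=0)
    p = 2.0 * np.minimum(n_ge + 1, n_le + 1) / (n_null + 1)
    p = np.minimum(p, 1.0)
    p[degenerate] = np.nan
    idx = plot_index if plot_index is not None else pd.RangeIndex(W.shape[0])
    table = pd.DataFrame({"observed": obs, "null_mean": mean, "null_sd": sd,
                          "z": z, "p": p, "degenerate": degenerate}, index=idx)
    return SESResult(metric=metric, table=table, n_null=n_null)


# ------------------------------------------------- discriminability summary

def discriminability_summary(loci, threshold: float):
    """(mean pairwise locus distance, fraction of pairs at/above threshold).

    ``loci`` is an (n, d) array of color-space coordinates (hexagon d=2,
    tetrahedron d=3); distances in the space's own units (HU or JND-free
    coordinates — pass receptor-noise distances directly if JND pairs are
    wanted).
    """
    pts = np.asarray(loci, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("need at least two loci")
    from scipy.spatial.distance import pdist
    d = pdist(pts)
    return float(d.mean()), float((d >= threshold).mean())


def pairwise_contrast_summary(dist_matrix: np.ndarray, threshold: float):
    """Same summary from a precomputed pairwise distance/contrast matrix."""
    D = np.asarray(dist_matrix, dtype=float)
    if D.shape[0] < 2:
        raise ValueError("need at least two loci")
    v = D[np.triu_indices(D.shape[0], 1)]
    return float(v.mean()), float((v >= threshold).mean())


# ------------------------------------------------- model-style front end

@dataclass
class ColorDiversityModel:
    """SES MPD/MNTD analysis of a plot x species community against a trait
    distance matrix, statsmodels-style: construct, then :meth:`fit`.

    Parameters
    ----------
    W : DataFrame
        Binary plots x species occurrence matrix.
    D : DataFrame
        Species x species Gower (or other) distance matrix; index/columns
        must match ``W``'s species.
    metadata : DataFrame, optional
        Per-plot metadata (site, transect, elevation, vegetation) carried
        through to the results table.
    """

    W: pd.DataFrame
    D: pd.DataFrame
    metadata: pd.DataFrame | None = None
    min_richness: int = 2
    dropped_plots: list = field(default_factory=list)

    def __post_init__(self):
        missing = [s for s in self.W.columns if s not in self.D.index]
        if missing:
            raise ValueError(f"species missing from distance matrix: {missing[:5]}")
        self.D = self.D.loc[self.W.columns, self.W.columns]
        rich = (self.W.to_numpy() > 0).sum(axis=1)
        keep = rich >= self.min_richness
        self.dropped_plots = self.W.index[~keep].tolist()
        self.W = self.W.loc[keep]
        if self.metadata is not None:
            self.metadata = self.metadata.loc[self.W.index]

    def fit(self, metrics=("mpd", "mntd"), n_null: int = N_NULL_DEFAULT,
            seed=None) -> "DiversityResults":
        results = {}
        for i, metric in enumerate(metrics):
            s = None if seed is None else seed + i
            results[metric] = ses(metric, (self.W.to_numpy() > 0).astype(np.int8),
                                  self.D.to_numpy(), n_null=n_null, seed=s,
                                  plot_index=self.W.index)
        return DiversityResults(model=self, ses=results, n_null=n_null)


@dataclass
class DiversityResults:
    model: ColorDiversityModel
    ses: dict
    n_null: int

    def table(self, metric: str = "mpd") -> pd.DataFrame:
        t = self.ses[metric].table.copy()
        if self.model.metadata is not None:
            t = self.model.metadata.join(t)
        return t

    def summary(self) -> str:
        lines = [f"Color diversity SES ({self.n_null} swap randomizations, "
                 f"{len(self.model.W)} plots, {self.model.W.shape[1]} species)"]
        if self.model.dropped_plots:
            lines.append(f"  dropped {len(self.model.dropped_plots)} plots with "
                         f"richness < {self.model.min_richness}")
        for metric, res in self.ses.items():
            lines.append("  " + res.summary())
        return "\n".join(lines)
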