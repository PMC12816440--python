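"""Regression layer: OLS per-trait fits and the random-intercept linear
mixed model (transect as the random factor), with Nakagawa-Schielzeth
marginal and conditional R-squared.

Fitting is delegated to statsmodels (OLS, MixedLM/REML); this module adds
input checking, the variance decomposition, and table output shaped like
the reporting tables downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm


def ols(y, x):
    """Ordinary least squares of y on a single predictor (plus intercept).

    Returns the statsmodels results object (params, pvalues, rsquared...).
    """
    y = np.asarray(y, dtype=float)
    X = np.column_stack([np.ones(len(y)), np.asarray(x, dtype=float)])
    if len(y) <= np.linalg.matrix_rank(X):
        raise ValueError("not enough observations for the design rank")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design (constant predictor?)")
    return sm.OLS(y, X).fit()


@dataclass
class LmmFit:
    """Random-intercept mixed-model fit.

    Attributes hold fixed-effect estimates with Wald t statistics, the two
    variance components, and the Nakagawa-Schielzeth R-squareds:
    marginal = var(fixed) / (var(fixed) + var(group) + var(resid)),
    conditional = (var(fixed) + var(group)) / (same denominator).
    """

    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    group_var: float
    resid_var: float
    marginal_r2: float
    conditional_r2: float
    n_groups: int
    converged: bool
    fallback_ols: bool = False

    def table(self) -> pd.DataFrame:
        """Term / Estimate / Error / t / P / Marginal R2 / Conditional R2."""
        return pd.DataFrame({
            "Term": self.params.index,
            "Estimate": self.params.to_numpy(),
            "Error": self.bse.to_numpy(),
            "t": self.tvalues.to_numpy(),
            "P": self.pvalues.to_numpy(),
            "Marginal R2": self.marginal_r2,
            "Conditional R2": self.conditional_r2,
        })

    def summary(self) -> str:
        lines = [f"Random-intercept LMM ({self.n_groups} groups; "
                 f"sigma2_group = {self.group_var:.4f}, "
                 f"sigma2_resid = {self.resid_var:.4f})"]
        if self.fallback_ols:
            lines[0] += " [single group: OLS fallback]"
        lines.append(self.table().to_string(index=False,
                                            float_format=lambda v: f"{v:.4f}"))
        return "\n".join(lines)


def lmm_random_intercept(y, X: pd.DataFrame, group) -> LmmFit:
    """REML fit of y ~ X with a random intercept per level of ``group``.

    With a single group the random effect is unidentifiable; the fit falls
    back to OLS with a warning (group variance reported as 0).
    """
    y = np.asarray(y, dtype=float)
    X = pd.DataFrame(X).astype(float)
    Xd = sm.add_constant(X)
    Xd = Xd.rename(columns={"const": "(Intercept)"})
    groups = pd.Series(group).astype(str).to_numpy()
    n_groups = len(np.unique(groups))
    if len(y) <= Xd.shape[1] + 1:
        raise ValueError("not enough observations")
    if n_groups < 2:
        warnings.warn("single group: falling back to OLS (no random effect)")
        fit = sm.OLS(y, Xd).fit()
        fitted_fixed = np.asarray(fit.fittedvalues)
        var_f = float(np.var(fitted_fixed))
        var_e = float(fit.scale)
        denom = var_f + var_e
        return LmmFit(params=fit.params, bse=fit.bse, tvalues=fit.tvalues,
                      pvalues=fit.pvalues, group_var=0.0, resid_var=var_e,
                      marginal_r2=var_f / denom, conditional_r2=var_f / denom,
                      n_groups=1, converged=True, fallback_ols=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, Xd, groups=groups)
        fit = model.fit(reml=True)
    var_g = float(np.squeeze(fit.cov_re))
    var_e = float(fit.scale)
    fe = fit.fe_params
    fitted_fixed = Xd.to_numpy() @ fe.to_numpy()
    var_f = float(np.var(fitted_fixed))
    denom = var_f + var_g + var_e
    params = pd.Series(fe.to_numpy(), index=Xd.columns)
    bse = pd.Series(fit.bse_fe.to_numpy(), index=Xd.columns)
    tvals = params / bse
    pvals = pd.Series(np.asarray(fit.pvalues)[: len(params)], index=Xd.columns)
    marginal = var_f / denom
    conditional = (var_f + var_g) / denom
    return LmmFit(params=params, bse=bse, tvalues=tvals, pvalues=pvals,
                  group_var=var_g, resid_var=var_e,
                  marginal_r2=marginal, conditional_r2=conditional,
                  n_groups=n_groups, converged=bool(fit.converged))


def diversity_lmm(ses_table: pd.DataFrame, response: str = "z",
                  elevation_col: str = "elevation",
                  vegetation_col: str = "vegetation",
                  transect_col: str = "transect",
                  reference_level: str = "RO") -> LmmFit:
    """Table-3-shaped model: SES z ~ elevation + vegetation, random
    intercept per transect, vegetation coded against ``reference_level``."""
    df = ses_table.dropna(subset=[response]).copy()
    veg = pd.Categorical(df[vegetation_col])
    if reference_level in veg.categories:
        veg = veg.reorder_categories(
            [reference_level] + [c for c in veg.categories if c != reference_level])
    dummies = pd.get_dummies(pd.Series(veg, index=df.index), drop_first=True,
                             dtype=float)
    X = pd.concat([df[[elevation_col]].rename(columns={elevation_col: "Elevation"}),
                   dummies], axis=1)
    return lmm_random_intercept(df[response].to_numpy(), X, df[transect_col])
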