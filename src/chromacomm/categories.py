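"""Categorical color traits and color x pollination-system association tests.

UV class is computed from the spectra (mean reflectance over 300-400 nm
against a documented threshold); human color names, floral guides and
pollen/anther-mimicry flags are observer-supplied input labels. The
association layer cross-tabulates color classes against pollination
systems and tests them with a G-test and a (simple or constrained)
correspondence analysis with a permutation p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .spectra import Spectrum

#: a flower part is UV-reflecting if its mean reflectance over 300-400 nm
#: is at or above this fraction
UV_THRESHOLD = 0.10
UV_BAND = (300.0, 400.0)


def classify_uv(spectrum: Spectrum, threshold: float = UV_THRESHOLD) -> str:
    """"UV-reflecting" iff mean reflectance over 300-400 nm >= threshold."""
    wl = spectrum.wavelengths
    mask = (wl >= UV_BAND[0]) & (wl <= UV_BAND[1])
    if not mask.any():
        raise ValueError("spectrum does not cover the 300-400 nm UV band")
    mean_uv = float(spectrum.values[mask].mean())
    return "UV-reflecting" if mean_uv >= threshold else "UV-absorbing"


def detect_uv_pattern(periphery: Spectrum, center: Spectrum | None,
                      threshold: float = UV_THRESHOLD):
    """True iff periphery and center fall in different UV classes.

    Returns True/False, or None ("unknown") when the center spectrum is
    missing — absence of evidence is not evidence of no pattern.
    """
    if center is None:
        return None
    return classify_uv(periphery, threshold) != classify_uv(center, threshold)


def build_contingency(traits: pd.DataFrame, color_col: str,
                      system_col: str = "pollination_system",
                      weights: str = "species",
                      occurrence=None) -> pd.DataFrame:
    """Cross-tabulate a color class against pollination system.

    ``weights="species"`` counts each species once; ``weights="records"``
    weights each species by its number of occurrence records (requires
    ``occurrence``: a mapping or Series of species -> record count).
    """
    if color_col not in traits.columns or system_col not in traits.columns:
        raise ValueError(f"missing column: need {color_col!r} and {system_col!r}")
    if traits[color_col].isna().any() or traits[system_col].isna().any():
        raise ValueError("unknown (missing) category label in traits table")
    if weights == "species":
        w = pd.Series(1, index=traits.index)
    elif weights == "records":
        if occurrence is None:
            raise ValueError("weights='records' requires per-species occurrence counts")
        occ = pd.Series(occurrence)
        w = traits["species"].map(occ).fillna(0).astype(float)
    else:
        raise ValueError("weights must be 'species' or 'records'")
    return pd.crosstab(traits[color_col], traits[system_col],
                       values=w, aggfunc="sum", dropna=False).fillna(0.0)


def g_test(table: pd.DataFrame):
    """Log-likelihood-ratio test of independence, G = 2 sum O ln(O/E).

    Returns (G, df, p). Zero expected counts are rejected with guidance
    to pool sparse categories first.
    """
    obs = np.asarray(table, dtype=float)
    if obs.sum() <= 0:
        raise ValueError("empty contingency table")
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    expected = row @ col / obs.sum()
    if np.any(expected <= 0):
        raise ValueError("zero expected count; pool sparse categories before testing")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(obs > 0, obs * np.log(obs / expected), 0.0)
    g = 2.0 * float(terms.sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(stats.chi2.sf(g, df)) if df > 0 else float("nan")
    return g, df, p


@dataclass
class CAResult:
    """Simple correspondence analysis of a contingency table."""

    row_scores: pd.DataFrame
    col_scores: pd.DataFrame
    inertia: np.ndarray          # per-axis principal inertia
    total_inertia: float         # chi-square / N
    inertia_fraction: np.ndarray
    p_value: float | None = None

    def summary(self) -> str:
        lines = ["Correspondence analysis",
                 f"  total inertia (chi2/N): {self.total_inertia:.6f}"]
        for i, (lam, fr) in enumerate(zip(self.inertia, self.inertia_fraction), 1):
            lines.append(f"  axis {i}: inertia {lam:.6f} ({100 * fr:.1f}%)")
        if self.p_value is not None:
            lines.append(f"  permutation p = {self.p_value:.4f}")
        return "\n".join(lines)


def _ca_decompose(obs: np.ndarray):
    n = obs.sum()
    P = obs / n
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    if np.any(r <= 0) or np.any(c <= 0):
        raise ValueError("zero row or column margin")
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sv, Vt = np.linalg.svd(S, full_matrices=False)
    return U, sv, Vt, r, c


def correspondence_analysis(table: pd.DataFrame, n_axes: int | None = None,
                            n_perm: int = 999, seed: int | None = None,
                            constraints: pd.DataFrame | None = None) -> CAResult:
    """SVD of the standardized-residual matrix (simple CA).

    Per-axis principal inertias are the squared singular values; their sum
    equals chi-square / N. The permutation p-value compares total inertia
    against tables built by shuffling the column (pollination-system)
    labels of the underlying records. ``constraints`` switches to a
    constrained (CCA-like) mode: row profiles are first projected onto the
    column space of the standardized predictor matrix (rows aligned with
    the table's rows) and the residual decomposition proceeds on the
    projected part.
    """
    obs = np.asarray(table, dtype=float)
    if obs.sum() <= 0 or min(obs.shape) < 2:
        raise ValueError("contingency table must be at least 2x2 with positive total")
    work = obs
    if constraints is not None:
        Z = np.asarray(constraints, dtype=float)
        if Z.shape[0] != obs.shape[0]:
            raise ValueError("constraint rows must align with table rows")
        Z = np.column_stack([np.ones(Z.shape[0]), Z])
        H = Z @ np.linalg.pinv(Z)
        work = H @ obs
        work = np.clip(work, 0, None)
        if work.sum() <= 0:
            raise ValueError("constrained projection produced an empty table")
    U, sv, Vt, r, c = _ca_decompose(work)
    rank = min(work.shape) - 1
    sv = sv[:rank]
    if n_axes is not None:
        rank = min(rank, n_axes)
    inertia = sv ** 2
    total = float(inertia.sum())
    frac = inertia / total if total > 0 else np.zeros_like(inertia)
    row_pc = (U[:, :rank] * sv[:rank]) / np.sqrt(r)[:, None]
    col_pc = (Vt[:rank].T * sv[:rank]) / np.sqrt(c)[:, None]
    axes = [f"CA{i + 1}" for i in range(rank)]
    res = CAResult(
        row_scores=pd.DataFrame(row_pc[:, :rank], index=table.index, columns=axes),
        col_scores=pd.DataFrame(col_pc[:, :rank], index=table.columns, columns=axes),
        inertia=inertia[:rank] if n_axes else inertia,
        total_inertia=total,
        inertia_fraction=frac[:rank] if n_axes else frac,
    )
    if n_perm and n_perm > 0:
        rng = np.random.default_rng(seed)
        # expand the table to individual records and permute column labels
        counts = np.rint(obs).astype(int)
        rows = np.repeat(np.arange(obs.shape[0]), counts.sum(axis=1))
        cols = np.concatenate([
            np.repeat(np.arange(obs.shape[1]), counts[i]) for i in range(obs.shape[0])
        ])
        null = np.empty(n_perm)
        for b in range(n_perm):
            perm_cols = rng.permutation(cols)
            tab = np.zeros_like(obs)
            np.add.at(tab, (rows, perm_cols), 1)
            _, sv_b, _, _, _ = _ca_decompose(tab)
            null[b] = float((sv_b[:min(obs.shape) - 1] ** 2).sum())
        res.p_value = float((np.sum(null >= total) + 1) / (n_perm + 1))
    return res


def uv_class_table(spectra_by_species: dict, threshold: float = UV_THRESHOLD) -> pd.Series:
    """UV class per species from periphery spectra."""
    return pd.Series({sp: classify_uv(s, threshold)
                      for sp, s in spectra_by_species.items()}, name="uv_class")
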