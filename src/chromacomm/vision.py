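"""Shared machinery of the bee and bird visual models.

Receptor sensitivities are generated from the Govardovskii A1 visual-pigment
nomogram (alpha band plus optional beta band), peak-normalized to 1; the
ambient light is the CIE D65 standard daylight; quantum catches are
trapezoidal integrals of reflectance x sensitivity x illuminant; chromatic
adaptation is the von Kries normalization by the catches of the leaf-green
background.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .spectra import Spectrum

# Bundled default lambda_max (nm). Bee: bumblebee-type trichromat
# (UV / blue / green); bird: UVS-type tetrachromat (UV / short / medium /
# long) with the double cone modelled by the long-wavelength template.
BEE_LAMBDA_MAX = {"uv": 328.0, "blue": 428.0, "green": 536.0}
BIRD_LAMBDA_MAX = {"uv": 355.0, "s": 450.0, "m": 540.0, "l": 605.0}

# Weber fractions. Bird noise follows the neural-noise regime with relative
# cone abundances u:s:m:l = 1:2:2:4 and e_l = 0.1, e_i = 0.1*sqrt(n_l/n_i).
BEE_WEBER = {"uv": 0.13, "blue": 0.06, "green": 0.12}
_BIRD_ABUND = {"uv": 1.0, "s": 2.0, "m": 2.0, "l": 4.0}
BIRD_WEBER = {k: 0.1 * np.sqrt(_BIRD_ABUND["l"] / n) for k, n in _BIRD_ABUND.items()}
DOUBLE_CONE_WEBER = 0.2


def pigment_template(lambda_max: float, grid: np.ndarray,
                     beta_band: bool = True) -> Spectrum:
    """A1 visual-pigment nomogram evaluated on ``grid``, peak-normalized.

    Alpha band: S(x) = 1 / (exp[A(a-x)] + exp[B(b-x)] + exp[C(c-x)] + D)
    with x = lambda_max / lambda, A=69.7, B=28, C=-14.9, D=0.674,
    b=0.922, c=1.104 and a = 0.8795 + 0.0459 exp(-(lambda_max-300)^2/11940).
    Beta band: 0.26 exp(-((lambda - (189 + 0.315 lmax)) / (-40.5 + 0.195 lmax))^2).
    """
    if not (300.0 <= lambda_max <= 650.0):
        raise ValueError(f"lambda_max {lambda_max} outside supported range [300, 650] nm")
    lam = np.asarray(grid, dtype=float)
    x = lambda_max / lam
    a = 0.8795 + 0.0459 * np.exp(-((lambda_max - 300.0) ** 2) / 11940.0)
    alpha = 1.0 / (
        np.exp(69.7 * (a - x))
        + np.exp(28.0 * (0.922 - x))
        + np.exp(-14.9 * (1.104 - x))
        + 0.674
    )
    s = alpha
    if beta_band:
        lm_beta = 189.0 + 0.315 * lambda_max
        b_beta = -40.5 + 0.195 * lambda_max
        s = s + 0.26 * np.exp(-(((lam - lm_beta) / b_beta) ** 2))
    s = s / s.max()
    return Spectrum(lam, s, role="sensitivity", label=f"template_{lambda_max:g}nm")


def d65_illuminant(grid: np.ndarray) -> Spectrum:
    """CIE D65 daylight interpolated onto ``grid``, normalized to 1 at 560 nm."""
    lam = np.asarray(grid, dtype=float)
    if lam[0] < 300.0 - 1e-9 or lam[-1] > 830.0 + 1e-9:
        raise ValueError("D65 table covers 300-830 nm; requested grid outside")
    tab = _d65_table()
    vals = np.interp(lam, tab["wavelength_nm"].to_numpy(), tab["relative_power"].to_numpy())
    ref = np.interp(560.0, tab["wavelength_nm"].to_numpy(), tab["relative_power"].to_numpy())
    return Spectrum(lam, vals / ref, role="illuminant", label="D65")


def _d65_table() -> pd.DataFrame:
    with resources.files("chromacomm.data").joinpath("cie_d65.csv").open() as fh:
        return pd.read_csv(fh)


@dataclass(frozen=True)
class ReceptorSet:
    """Ordered receptor sensitivities with Weber fractions.

    ``achromatic`` optionally names a receptor used for the achromatic
    channel (the avian double cone).
    """

    name: str
    labels: tuple
    sensitivities: tuple  # of Spectrum
    weber: tuple
    achromatic_label: str | None = None
    achromatic_sensitivity: Spectrum | None = None
    achromatic_weber: float | None = None

    def __post_init__(self):
        if len(self.labels) != len(self.sensitivities) or len(self.labels) != len(self.weber):
            raise ValueError("labels, sensitivities and weber fractions must align")
        if any(w <= 0 for w in self.weber):
            raise ValueError("Weber fractions must be positive")
        for s in self.sensitivities:
            if s.values.min() < 0 or not np.isclose(s.values.max(), 1.0):
                raise ValueError("sensitivities must be nonnegative and peak-normalized")

    @property
    def n(self) -> int:
        return len(self.labels)


def bee_receptors(grid: np.ndarray, lambda_max: dict | None = None,
                  weber: dict | None = None) -> ReceptorSet:
    lmax = dict(BEE_LAMBDA_MAX, **(lambda_max or {}))
    web = dict(BEE_WEBER, **(weber or {}))
    labels = ("uv", "blue", "green")
    return ReceptorSet(
        name="bee_trichromat",
        labels=labels,
        sensitivities=tuple(pigment_template(lmax[k], grid) for k in labels),
        weber=tuple(web[k] for k in labels),
    )


def bird_receptors(grid: np.ndarray, lambda_max: dict | None = None,
                   weber: dict | None = None,
                   double_cone_weber: float = DOUBLE_CONE_WEBER) -> ReceptorSet:
    lmax = dict(BIRD_LAMBDA_MAX, **(lambda_max or {}))
    web = dict(BIRD_WEBER, **(weber or {}))
    labels = ("uv", "s", "m", "l")
    return ReceptorSet(
        name="bird_uvs_tetrachromat",
        labels=labels,
        sensitivities=tuple(pigment_template(lmax[k], grid) for k in labels),
        weber=tuple(web[k] for k in labels),
        achromatic_label="double",
        achromatic_sensitivity=pigment_template(lmax["l"], grid),
        achromatic_weber=double_cone_weber,
    )


def quantum_catch(reflectance: Spectrum, sensitivity: Spectrum,
                  illuminant: Spectrum) -> float:
    """Q = integral of R(lam) S(lam) I(lam) dlam (trapezoidal rule)."""
    if not (reflectance.on_grid(sensitivity) and reflectance.on_grid(illuminant)):
        raise ValueError("grid mismatch between reflectance, sensitivity, illuminant")
    integrand = reflectance.values * sensitivity.values * illuminant.values
    return float(np.trapezoid(integrand, reflectance.wavelengths))


def catches(reflectance: Spectrum, receptors: ReceptorSet,
            illuminant: Spectrum) -> np.ndarray:
    return np.array([quantum_catch(reflectance, s, illuminant)
                     for s in receptors.sensitivities])


def von_kries(Q: np.ndarray, Q_bg: np.ndarray) -> np.ndarray:
    """Relative catches q_i = Q_i / Q_i(background)."""
    Q = np.asarray(Q, dtype=float)
    Q_bg = np.asarray(Q_bg, dtype=float)
    if Q.shape != Q_bg.shape:
        raise ValueError("catch vectors must share shape")
    if np.any(Q_bg <= 0):
        raise ValueError("background quantum catch must be positive for every receptor")
    return Q / Q_bg


@dataclass(frozen=True)
class QuantumCatch:
    """Raw and background-relative (von Kries) catches for one stimulus."""

    raw: np.ndarray
    relative: np.ndarray


def stimulus_catches(reflectance: Spectrum, background: Spectrum,
                     receptors: ReceptorSet, illuminant: Spectrum) -> QuantumCatch:
    raw = catches(reflectance, receptors, illuminant)
    bg = catches(background, receptors, illuminant)
    return QuantumCatch(raw=raw, relative=von_kries(raw, bg))
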