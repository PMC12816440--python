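"""Bee (trichromat) perceptual color variables.

The color hexagon maps the three receptor excitations E = q/(q+1) to a
plane in which the adapting background sits at the origin and the three
receptor vertices plus their midpoints span a regular hexagon of
circumradius 1. Distances are in hexagon units (HU); the conventional
bee discrimination threshold is 0.2 HU.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .spectra import Spectrum
from .vision import ReceptorSet, stimulus_catches

#: radius below which a locus is treated as achromatic (hue undefined)
ACHROMATIC_RADIUS = 0.05

#: bee discrimination threshold in hexagon units
BEE_THRESHOLD_HU = 0.2

#: spectrum-locus construction: narrowband Gaussians, FWHM 10 nm, peak 1,
#: tabulated every nm over this range (bee spectrum loci end near 550 nm)
SPECTRUM_LOCUS_RANGE = (300.0, 550.0)
NARROWBAND_FWHM = 10.0

CATEGORY_NAMES = ("blue", "blue-green", "green", "uv-green", "uv", "uv-blue")


def bee_excitation(q) -> np.ndarray:
    """Receptor excitation E = q / (q + 1); background (q=1) gives E=0.5."""
    q = np.asarray(q, dtype=float)
    if np.any(q < 0):
        raise ValueError("relative quantum catch must be nonnegative")
    return q / (q + 1.0)


def hexagon_locus(e_uv: float, e_b: float, e_g: float) -> tuple:
    """Hexagon coordinates: x = (sqrt3/2)(E_g - E_uv), y = E_b - (E_uv + E_g)/2."""
    x = (math.sqrt(3.0) / 2.0) * (e_g - e_uv)
    y = e_b - (e_uv + e_g) / 2.0
    return (x, y)


def chromatic_contrast_hu(a, b) -> float:
    """Euclidean distance between two hexagon loci, in HU."""
    return float(math.hypot(a[0] - b[0], a[1] - b[1]))


def green_contrast(e_g: float) -> float:
    """Achromatic (green-receptor) contrast to the background, |E_g - 0.5|."""
    if not (0.0 <= e_g <= 1.0):
        raise ValueError("green excitation must lie in [0, 1]")
    return abs(e_g - 0.5)


def brightness_bee(q, mode: str = "catch_sum", reflectance: Spectrum | None = None) -> float:
    """Bee brightness: sum of relative catches (default) or mean reflectance."""
    if mode == "catch_sum":
        return float(np.sum(np.asarray(q, dtype=float)))
    if mode == "mean_reflectance":
        if reflectance is None:
            raise ValueError("mean_reflectance mode needs the reflectance spectrum")
        return float(reflectance.values.mean())
    raise ValueError(f"unknown brightness mode {mode!r}")


def hue_angle(locus) -> float:
    """Hue angle in degrees measured from the +y (blue-vertex) direction,
    increasing toward the green vertex, in (-180, 180]."""
    ang = math.degrees(math.atan2(locus[0], locus[1]))
    if ang <= -180.0:
        ang += 360.0
    return ang


def _circ_diff(a: float, b: float) -> float:
    d = (a - b) % 360.0
    return d - 360.0 if d > 180.0 else d


@dataclass(frozen=True)
class SpectrumLocusTable:
    """Hexagon loci of narrowband (monochromatic-like) stimuli per nm."""

    wavelengths: np.ndarray
    angles: np.ndarray  # hue angle, degrees
    radii: np.ndarray   # HU


def spectrum_locus_table(background: Spectrum, receptors: ReceptorSet,
                         illuminant: Spectrum,
                         lo: float = SPECTRUM_LOCUS_RANGE[0],
                         hi: float = SPECTRUM_LOCUS_RANGE[1],
                         fwhm: float = NARROWBAND_FWHM) -> SpectrumLocusTable:
    grid = background.wavelengths
    sigma = fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    wls = np.arange(lo, hi + 0.5, 1.0)
    angles = np.empty_like(wls)
    radii = np.empty_like(wls)
    # vectorized: narrowband Gaussian reflectance peaked at each wl
    sens = np.vstack([s.values for s in receptors.sensitivities])
    illum = illuminant.values
    bg_q = np.array([np.trapezoid(background.values * s * illum, grid) for s in sens])
    for i, wl in enumerate(wls):
        refl = np.exp(-((grid - wl) ** 2) / (2.0 * sigma ** 2))
        q = np.array([np.trapezoid(refl * s * illum, grid) for s in sens]) / bg_q
        e = bee_excitation(q)
        x, y = hexagon_locus(*e)
        angles[i] = hue_angle((x, y))
        radii[i] = math.hypot(x, y)
    return SpectrumLocusTable(wavelengths=wls, angles=angles, radii=radii)


def dominant_wavelength(locus, table: SpectrumLocusTable):
    """Wavelength of the spectrum-locus entry with the nearest hue angle.

    Returns (wavelength_nm, flag) where flag is None, "achromatic" (radius
    below threshold) or "purple-line" (hue falls in the angular gap between
    the spectrum-locus endpoints, i.e. a UV/long-wave mixture).
    """
    r = math.hypot(locus[0], locus[1])
    if r < ACHROMATIC_RADIUS:
        return (None, "achromatic")
    ang = hue_angle(locus)
    diffs = np.abs([_circ_diff(ang, a) for a in table.angles])
    idx = int(np.argmin(diffs))
    # gap between the endpoints (arc not covered by the locus): if the hue is
    # closer to slipping past an endpoint than to any interior point, and lies
    # between the two endpoint angles on the uncovered side, flag purple-line.
    a_lo, a_hi = table.angles[0], table.angles[-1]
    if idx in (0, len(table.angles) - 1):
        end = table.angles[idx]
        inner = table.angles[1] if idx == 0 else table.angles[-2]
        step = abs(_circ_diff(end, inner))
        off = _circ_diff(ang, end)
        # does `ang` sit on the side of the endpoint away from the locus?
        inner_side = math.copysign(1.0, _circ_diff(inner, end)) if step > 0 else 0.0
        if off != 0.0 and math.copysign(1.0, off) != inner_side and abs(off) > step:
            return (None, "purple-line")
    return (float(table.wavelengths[idx]), None)


def spectral_purity_bee(locus, table: SpectrumLocusTable):
    """r(stimulus) / r(narrowband stimulus at the dominant wavelength)."""
    wl, flag = dominant_wavelength(locus, table)
    if flag is not None:
        return (None, flag)
    idx = int(np.argmin(np.abs(table.wavelengths - wl)))
    r = math.hypot(locus[0], locus[1])
    r_mono = table.radii[idx]
    return (min(r / r_mono, 1.0), None)


def bee_color_category(locus) -> str:
    """Hexagon sector of the hue angle: six 60-degree sectors centered on the
    three receptor vertices (blue at 0, green at 120, UV at 240) and their
    midpoints. Boundary angles go to the counter-clockwise sector; loci with
    radius below the achromatic threshold are labelled "achromatic"."""
    r = math.hypot(locus[0], locus[1])
    if r < ACHROMATIC_RADIUS:
        return "achromatic"
    ang = hue_angle(locus)
    # sectors are (center-30, center+30]; ceil implements the CCW tie-break
    k = int(math.ceil((ang - 30.0) / 60.0)) % 6
    return CATEGORY_NAMES[k]


@dataclass(frozen=True)
class BeeVariables:
    """Per-stimulus bee color variables (the bee trait columns)."""

    q_uv: float
    q_blue: float
    q_green: float
    e_uv: float
    e_blue: float
    e_green: float
    x: float
    y: float
    r: float
    chromatic_contrast_bg: float
    green_contrast: float
    brightness: float
    dominant_wavelength: float | None
    dominant_flag: str | None
    spectral_purity: float | None
    category: str


def bee_variables(reflectance: Spectrum, background: Spectrum,
                  receptors: ReceptorSet, illuminant: Spectrum,
                  locus_table: SpectrumLocusTable | None = None,
                  brightness_mode: str = "catch_sum") -> BeeVariables:
    """Full bee pipeline for one flower spectrum against the leaf background."""
    qc = stimulus_catches(reflectance, background, receptors, illuminant)
    e = bee_excitation(qc.relative)
    x, y = hexagon_locus(*e)
    if locus_table is None:
        locus_table = spectrum_locus_table(background, receptors, illuminant)
    wl, flag = dominant_wavelength((x, y), locus_table)
    purity, _ = spectral_purity_bee((x, y), locus_table)
    return BeeVariables(
        q_uv=qc.relative[0], q_blue=qc.relative[1], q_green=qc.relative[2],
        e_uv=e[0], e_blue=e[1], e_green=e[2],
        x=x, y=y, r=math.hypot(x, y),
        chromatic_contrast_bg=chromatic_contrast_hu((x, y), (0.0, 0.0)),
        green_contrast=green_contrast(e[2]),
        brightness=brightness_bee(qc.relative, mode=brightness_mode,
                                  reflectance=reflectance),
        dominant_wavelength=wl, dominant_flag=flag,
        spectral_purity=purity,
        category=bee_color_category((x, y)),
    )
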