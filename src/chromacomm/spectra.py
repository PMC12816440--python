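"""Reflectance spectrum containers and basic processing.

A :class:`Spectrum` holds one measured curve (flower part, leaf, illuminant
or receptor sensitivity) on a strictly increasing wavelength grid in nm.
All downstream color models operate on a shared uniform *working grid*,
by default 300–700 nm at 1-nm steps — the window relevant to bee and
avian photoreceptors.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: default working grid bounds and step (nm)
WORKING_LO = 300.0
WORKING_HI = 700.0
WORKING_STEP = 1.0

#: reflectance more negative than this is treated as a data error,
#: values in (-NEGATIVE_TOL, 0) are instrument noise and clipped to 0
NEGATIVE_TOL = 0.05

ROLES = ("flower_periphery", "flower_center", "leaf", "illuminant", "sensitivity")


@dataclass(frozen=True)
class Spectrum:
    """One spectral curve on a strictly increasing wavelength grid."""

    wavelengths: np.ndarray
    values: np.ndarray
    role: str = "flower_periphery"
    label: str = ""

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if wl.ndim != 1 or v.shape != wl.shape:
            raise ValueError("wavelengths and values must be 1-D arrays of equal length")
        if wl.size < 2:
            raise ValueError("a spectrum needs at least two samples")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("non-monotone grid: wavelengths must be strictly increasing")
        if not (np.all(np.isfinite(wl)) and np.all(np.isfinite(v))):
            raise ValueError("non-finite wavelength or value in spectrum")
        if self.role not in ROLES:
            raise ValueError(f"unknown spectrum role {self.role!r}; expected one of {ROLES}")
        if self.role in ("flower_periphery", "flower_center", "leaf"):
            if v.min() < -NEGATIVE_TOL:
                raise ValueError(
                    f"reflectance {v.min():.3f} below tolerance -{NEGATIVE_TOL}"
                )
            if v.min() < 0:
                logger.warning(
                    "clipping %d slightly negative reflectance values to 0 (%s)",
                    int((v < 0).sum()), self.label,
                )
                v = np.clip(v, 0.0, None)
            if v.max() > 1.0:
                v = np.clip(v, None, 1.0)
        elif v.min() < 0:
            raise ValueError(f"{self.role} values must be nonnegative")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", v)

    @property
    def step(self) -> float:
        d = np.diff(self.wavelengths)
        return float(d[0]) if np.allclose(d, d[0]) else float("nan")

    def on_grid(self, other: "Spectrum") -> bool:
        return (
            self.wavelengths.shape == other.wavelengths.shape
            and bool(np.array_equal(self.wavelengths, other.wavelengths))
        )


def resample(s: Spectrum, lo: float = WORKING_LO, hi: float = WORKING_HI,
             step: float = WORKING_STEP) -> Spectrum:
    """Linear interpolation of ``s`` onto the uniform grid [lo, hi] with ``step``.

    Endpoints are included; the requested range must lie within the
    spectrum's native range (no extrapolation).
    """
    if lo >= hi or step <= 0:
        raise ValueError("need lo < hi and step > 0")
    if lo < s.wavelengths[0] - 1e-9 or hi > s.wavelengths[-1] + 1e-9:
        raise ValueError(
            f"requested range [{lo}, {hi}] outside native range "
            f"[{s.wavelengths[0]}, {s.wavelengths[-1]}]"
        )
    n = int(round((hi - lo) / step))
    grid = lo + step * np.arange(n + 1)
    if s.step == step and grid.size == s.wavelengths.size and np.allclose(grid, s.wavelengths):
        return s
    vals = np.interp(grid, s.wavelengths, s.values)
    return replace(s, wavelengths=grid, values=vals)


def smooth(s: Spectrum, window_nm: float = 5.0) -> Spectrum:
    """Boxcar smoothing (off by default in the pipeline); edge-padded."""
    step = s.step
    if not np.isfinite(step):
        raise ValueError("smooth requires a uniform grid; resample first")
    w = max(1, int(round(window_nm / step)))
    if w % 2 == 0:
        w += 1
    if w == 1:
        return s
    pad = w // 2
    padded = np.pad(s.values, pad, mode="edge")
    kernel = np.ones(w) / w
    vals = np.convolve(padded, kernel, mode="valid")
    return replace(s, values=vals)


@dataclass
class SpectrumSet:
    """Collection of spectra keyed by (species, part, replicate)."""

    spectra: dict = field(default_factory=dict)  # (species, part, replicate) -> Spectrum

    def add(self, species: str, part: str, replicate: str, spectrum: Spectrum) -> None:
        self.spectra[(species, part, replicate)] = spectrum

    def __len__(self):
        return len(self.spectra)

    def __iter__(self):
        return iter(self.spectra.items())

    def keys(self):
        return self.spectra.keys()

    def resample_all(self, lo: float = WORKING_LO, hi: float = WORKING_HI,
                     step: float = WORKING_STEP) -> "SpectrumSet":
        return SpectrumSet({k: resample(s, lo, hi, step) for k, s in self.spectra.items()})

    def shared_grid(self) -> np.ndarray:
        grids = [s.wavelengths for s in self.spectra.values()]
        if not grids:
            raise ValueError("empty SpectrumSet")
        for g in grids[1:]:
            if not np.array_equal(g, grids[0]):
                raise ValueError("spectra do not share a common grid; resample first")
        return grids[0]

    def select(self, species=None, part=None):
        out = SpectrumSet()
        for (sp, pt, rep), s in self.spectra.items():
            if species is not None and sp != species:
                continue
            if part is not None and pt != part:
                continue
            out.spectra[(sp, pt, rep)] = s
        return out


def read_spectra(path, layout: str = "wide", role: str = "flower_periphery") -> SpectrumSet:
    """Read a CSV of reflectance spectra.

    ``wide``: first column ``wavelength_nm``, one spectrum per further column
    (column name used as species id, part taken from ``role``).
    ``long``: columns ``sample_id, species, part, wavelength_nm, reflectance``.
    """
    df = pd.read_csv(path)
    out = SpectrumSet()
    if layout == "wide":
        if "wavelength_nm" not in df.columns:
            raise ValueError("wide layout requires a 'wavelength_nm' column")
        wl = df["wavelength_nm"].to_numpy(float)
        for col in df.columns:
            if col == "wavelength_nm":
                continue
            s = Spectrum(wl, df[col].to_numpy(float), role=role,
                         label=f"{path}:{col}")
            out.add(str(col), _part_for_role(role), "1", s)
    elif layout == "long":
        required = {"sample_id", "species", "part", "wavelength_nm", "reflectance"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"long layout missing columns: {sorted(missing)}")
        for (sid, sp, part), grp in df.groupby(["sample_id", "species", "part"], sort=False):
            grp = grp.sort_values("wavelength_nm")
            r = "leaf" if part == "leaf" else role if part == _part_for_role(role) else (
                "flower_center" if part == "flower_center" else "flower_periphery")
            if part == "leaf":
                r = "leaf"
            s = Spectrum(grp["wavelength_nm"].to_numpy(float),
                         grp["reflectance"].to_numpy(float),
                         role=r, label=f"{path}:{sid}")
            out.add(str(sp), str(part), str(sid), s)
    else:
        raise ValueError("layout must be 'wide' or 'long'")
    return out


def _part_for_role(role: str) -> str:
    return {"flower_periphery": "flower_periphery",
            "flower_center": "flower_center",
            "leaf": "leaf"}.get(role, "flower_periphery")


def mean_spectrum(sset: SpectrumSet, species=None, part=None) -> Spectrum:
    """Pointwise arithmetic mean over the selected replicates.

    Replicate aggregation follows the convention of representing a species'
    flower color by the mean curve of its measured flowers; no outlier
    rejection is applied.
    """
    sel = sset.select(species=species, part=part)
    if len(sel) == 0:
        raise ValueError("empty group: no spectra match the selection")
    grid = sel.shared_grid()
    mat = np.vstack([s.values for _, s in sel])
    first = next(iter(sel.spectra.values()))
    return Spectrum(grid, mat.mean(axis=0), role=first.role,
                    label=f"mean({species or '*'},{part or '*'})")


def leaf_background(sset: SpectrumSet) -> Spectrum:
    """Grand mean of all leaf-role spectra: the adapting green background."""
    leaves = SpectrumSet({k: s for k, s in sset if s.role == "leaf"})
    if len(leaves) == 0:
        raise ValueError("no leaf spectra in set")
    out = mean_spectrum(leaves)
    return replace(out, role="leaf", label="leaf_background")
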