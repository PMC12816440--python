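"""Avian (tetrachromat) perceptual color variables.

Loci live in the regular tetrahedron of circumradius 0.75 whose vertices
are the four single-cone classes (UV on the +z axis); spectral purity is
the achieved chroma r / r_max along the locus direction; discriminability
is the receptor-noise-limited model in just-noticeable differences (JND),
with the achromatic channel carried by the double cone. The conventional
avian threshold used downstream is 0.1 JND.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .spectra import Spectrum
from .vision import ReceptorSet, quantum_catch, stimulus_catches, von_kries

#: bird discrimination threshold in JND
BIRD_THRESHOLD_JND = 0.1

_SQ22 = math.sqrt(2.0) / 2.0
#: vertex coordinates (u, s, m, l): circumradius 0.75, centroid at origin
TETRA_VERTICES = np.array([
    [0.0, 0.0, 0.75],
    [_SQ22 * math.cos(math.radians(90.0)), _SQ22 * math.sin(math.radians(90.0)), -0.25],
    [_SQ22 * math.cos(math.radians(210.0)), _SQ22 * math.sin(math.radians(210.0)), -0.25],
    [_SQ22 * math.cos(math.radians(330.0)), _SQ22 * math.sin(math.radians(330.0)), -0.25],
])

#: the four triangular faces (vertex index triples)
_FACES = list(combinations(range(4), 3))


def tetra_locus(q) -> np.ndarray:
    """Map four relative catches to tetrahedral coordinates.

    Catches are normalized to proportions summing to 1; the locus is the
    proportion-weighted average of the four vertices. Equal catches map to
    the origin (achromatic point); a pure single-cone stimulus maps to the
    corresponding vertex at distance 0.75.
    """
    q = np.asarray(q, dtype=float)
    if q.shape != (4,):
        raise ValueError("tetra_locus expects exactly four catches (u, s, m, l)")
    if np.any(q <= 0):
        raise ValueError("catches must be positive to form tetrahedral proportions")
    p = q / q.sum()
    return p @ TETRA_VERTICES


def achieved_chroma(locus) -> float:
    """r / r_max along the locus direction (ray-face intersection).

    Returns 0 at the achromatic origin and 1 on the tetrahedron boundary.
    """
    v = np.asarray(locus, dtype=float)
    r = float(np.linalg.norm(v))
    if r == 0.0:
        return 0.0
    d = v / r
    r_max = math.inf
    for face in _FACES:
        a, b, c = (TETRA_VERTICES[i] for i in face)
        n = np.cross(b - a, c - a)
        opposite = TETRA_VERTICES[[i for i in range(4) if i not in face][0]]
        if np.dot(n, opposite - a) > 0:  # orient normal outward
            n = -n
        denom = float(np.dot(n, d))
        if denom > 1e-12:
            t = float(np.dot(n, a)) / denom
            if t > 0:
                r_max = min(r_max, t)
    if not math.isfinite(r_max):
        raise ValueError("locus direction does not intersect the tetrahedron boundary")
    return min(r / r_max, 1.0)


def rn_chromatic_contrast(qA, qB, weber) -> float:
    """Receptor-noise-limited chromatic distance in JND (general n-receptor
    form of the Vorobyev-Osorio model, log-linear receptor signals).

    With Df_i = ln(qA_i / qB_i) and noise e_i:

        dS^2 = sum_{i<j} (prod_{k not in {i,j}} e_k)^2 (Df_i - Df_j)^2
               / sum_i (prod_{k != i} e_k)^2
    """
    qA = np.asarray(qA, dtype=float)
    qB = np.asarray(qB, dtype=float)
    e = np.asarray(weber, dtype=float)
    if qA.shape != qB.shape or qA.shape != e.shape:
        raise ValueError("catch vectors and Weber fractions must align")
    if np.any(qA <= 0) or np.any(qB <= 0):
        raise ValueError("catches must be positive (log receptor signals)")
    df = np.log(qA / qB)
    n = len(df)
    num = 0.0
    for i, j in combinations(range(n), 2):
        others = [k for k in range(n) if k not in (i, j)]
        num += np.prod(e[others]) ** 2 * (df[i] - df[j]) ** 2
    den = sum(np.prod(np.delete(e, i)) ** 2 for i in range(n))
    return float(math.sqrt(num / den))


def rn_achromatic_contrast(qA_double: float, qB_double: float,
                           e_double: float) -> float:
    """Double-cone achromatic contrast |ln(qA/qB)| / e, in JND."""
    if qA_double <= 0 or qB_double <= 0:
        raise ValueError("double-cone catches must be positive")
    if e_double <= 0:
        raise ValueError("double-cone Weber fraction must be positive")
    return abs(math.log(qA_double / qB_double)) / e_double


@dataclass(frozen=True)
class BirdVariables:
    """Per-stimulus avian color variables (the bird trait columns)."""

    q_uv: float
    q_s: float
    q_m: float
    q_l: float
    x: float
    y: float
    z: float
    r: float
    spectral_purity: float
    chromatic_contrast_bg: float
    achromatic_contrast_bg: float


def bird_variables(reflectance: Spectrum, background: Spectrum,
                   receptors: ReceptorSet, illuminant: Spectrum,
                   apply_von_kries: bool = True) -> BirdVariables:
    """Full avian pipeline for one flower spectrum against the leaf background."""
    qc = stimulus_catches(reflectance, background, receptors, illuminant)
    q = qc.relative if apply_von_kries else qc.raw
    # guard exact zeros (e.g. synthetic spectra that are 0 in a receptor band)
    q = np.maximum(q, 1e-9)
    locus = tetra_locus(q)
    bg_rel = np.ones(4) if apply_von_kries else None
    if bg_rel is None:
        bg_raw = np.array([quantum_catch(background, s, illuminant)
                           for s in receptors.sensitivities])
        bg_rel = bg_raw
    chrom = rn_chromatic_contrast(q, bg_rel, receptors.weber)
    qa = quantum_catch(reflectance, receptors.achromatic_sensitivity, illuminant)
    qb = quantum_catch(background, receptors.achromatic_sensitivity, illuminant)
    qa_rel = max(von_kries(np.array([qa]), np.array([qb]))[0], 1e-9)
    achro = rn_achromatic_contrast(qa_rel, 1.0, receptors.achromatic_weber)
    return BirdVariables(
        q_uv=q[0], q_s=q[1], q_m=q[2], q_l=q[3],
        x=locus[0], y=locus[1], z=locus[2], r=float(np.linalg.norm(locus)),
        spectral_purity=achieved_chroma(locus),
        chromatic_contrast_bg=chrom,
        achromatic_contrast_bg=achro,
    )
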