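"""Seeded synthetic datasets with the statistical structure the analyses
assume: smooth archetype flower spectra (with UV-reflecting/absorbing
variants and UV patterns), leaf-green background spectra, a five-site
plot/transect design along an 808-1427 m elevational gradient, pollination
system labels, a pure-birth phylogeny with Brownian traits, and community
assembly in neutral, convergent (environmental filtering) or divergent
(limiting similarity varying along the gradient) mode.

The defaults mirror the emulated field design: 5 sites x 36 one-square-
metre plots (four 250-m transects of 9 plots each), 179 species,
pollination mix 75% bee / 8% hummingbird / 17% other, and a color
inventory led by pink UV-absorbing, white UV-absorbing and yellow
UV-reflecting archetypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phylo import cophenetic_distances, simulate_bm, simulate_pure_birth
from .spectra import Spectrum, SpectrumSet

GRID = np.arange(300.0, 701.0, 1.0)

#: archetype relative frequencies (human color x UV class), led by the
#: three most prevalent combinations in the emulated inventory
ARCHETYPE_FREQS = {
    ("pink", "UV-absorbing"): 0.28,
    ("white", "UV-absorbing"): 0.18,
    ("yellow", "UV-reflecting"): 0.17,
    ("yellow", "UV-absorbing"): 0.08,
    ("red", "UV-absorbing"): 0.07,
    ("whitish", "UV-absorbing"): 0.07,
    ("white", "UV-reflecting"): 0.05,
    ("pink", "UV-reflecting"): 0.04,
    ("green", "UV-absorbing"): 0.04,
    ("whitish", "UV-reflecting"): 0.02,
}

VEGETATION_TYPES = ("CE", "RO", "SA", "ST", "WE")


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


#: visible-range shape parameters per human color archetype:
#: (long-pass edge nm, edge height, bump center nm, bump height, bump width nm, base)
_ARCHETYPE_SHAPES = {
    "pink": (590.0, 0.65, 440.0, 0.30, 45.0, 0.04),
    "white": (None, 0.0, None, 0.0, 0.0, 0.70),
    "whitish": (None, 0.0, None, 0.0, 0.0, 0.38),
    "yellow": (505.0, 0.80, None, 0.0, 0.0, 0.04),
    "red": (605.0, 0.70, None, 0.0, 0.0, 0.03),
    "green": (None, 0.0, 550.0, 0.35, 55.0, 0.05),
}

UV_REFLECTING_LEVEL = 0.20
UV_ABSORBING_LEVEL = 0.02


def _visible_shape(color: str) -> np.ndarray:
    if color not in _ARCHETYPE_SHAPES:
        raise ValueError(f"unknown archetype color {color!r}")
    edge, eh, bc, bh, bw, base = _ARCHETYPE_SHAPES[color]
    v = np.full_like(GRID, base)
    if edge is not None:
        v = v + eh * _logistic((GRID - edge) / 15.0)
    if bc is not None:
        v = v + bh * np.exp(-((GRID - bc) ** 2) / (2.0 * bw ** 2))
    return v


def gen_flower_spectrum(color: str, uv_class: str, rng,
                        noise_sd: float = 0.05,
                        center_uv_class: str | None = None):
    """Return (periphery, center) spectra for one simulated flower.

    The curve is a long-pass logistic edge and/or Gaussian bump archetype
    in the visible range, blended below ~400 nm into a high (UV-reflecting)
    or low (UV-absorbing) UV band, with multiplicative lognormal noise.
    ``center_uv_class`` differing from ``uv_class`` creates a UV pattern.
    """
    if uv_class not in ("UV-reflecting", "UV-absorbing"):
        raise ValueError(f"unknown UV class {uv_class!r}")
    blend = _logistic((GRID - 400.0) / 8.0)

    def one(uvc, role):
        uv_level = UV_REFLECTING_LEVEL if uvc == "UV-reflecting" else UV_ABSORBING_LEVEL
        v = blend * _visible_shape(color) + (1.0 - blend) * uv_level
        v = v * np.exp(rng.normal(0.0, noise_sd, size=v.shape))
        return Spectrum(GRID, np.clip(v, 0.0, 1.0), role=role)

    periphery = one(uv_class, "flower_periphery")
    center = one(center_uv_class or uv_class, "flower_center")
    return periphery, center


def gen_leaf_spectrum(rng, noise_sd: float = 0.05) -> Spectrum:
    """Leaf-green curve: low UV, chlorophyll green peak near 550 nm, red
    absorption, and the start of the near-infrared shoulder at 690-700 nm."""
    v = (0.04
         + 0.22 * np.exp(-((GRID - 550.0) ** 2) / (2.0 * 50.0 ** 2))
         + 0.45 * _logistic((GRID - 697.0) / 6.0))
    v = v * np.exp(rng.normal(0.0, noise_sd, size=v.shape))
    return Spectrum(GRID, np.clip(v, 0.0, 1.0), role="leaf")


@dataclass
class SimConfig:
    """Study-design parameters of the generator (defaults = emulated study)."""

    n_sites: int = 5
    plots_per_site: int = 36
    transects_per_site: int = 4
    elevation_range: tuple = (808.0, 1427.0)
    n_species: int = 179
    pollination_mix: dict = field(default_factory=lambda: {
        "bee": 0.75, "hummingbird": 0.08, "other": 0.17})
    assembly_mode: str = "neutral"  # neutral | convergent | divergent
    effect_size: float = 1.0
    mean_richness: float = 8.0
    envelope_sd: float = 150.0
    n_latent_traits: int = 2  # trait1 gradient-responsive, rest neutral BM
    n_flower_replicates: int = 10
    n_leaf_replicates: int = 10
    noise_sd: float = 0.05
    uv_pattern_fraction: float = 0.23
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.pollination_mix.values()) - 1.0) > 1e-9:
            raise ValueError("pollination mix proportions must sum to 1")
        if self.plots_per_site % self.transects_per_site != 0:
            raise ValueError("plots_per_site must divide evenly into transects")
        if self.assembly_mode not in ("neutral", "convergent", "divergent"):
            raise ValueError(f"unknown assembly mode {self.assembly_mode!r}")

    @classmethod
    def reduced(cls, **overrides) -> "SimConfig":
        """Small design for simulation batteries: 5 sites x 12 plots,
        40 species, 3 spectral replicates."""
        defaults = dict(n_sites=5, plots_per_site=12, transects_per_site=4,
                        n_species=40, n_flower_replicates=3,
                        n_leaf_replicates=3)
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class SyntheticCommunity:
    """Everything the pipeline consumes, generated from one seed."""

    config: SimConfig
    W: pd.DataFrame          # plots x species (0/1)
    env: pd.DataFrame        # plot metadata + environmental variables
    traits: pd.DataFrame     # species labels + latent numeric traits
    tree: object             # dendropy Tree
    P: pd.DataFrame          # cophenetic distances
    spectra: SpectrumSet     # flower periphery/center + leaf replicates

    @property
    def species(self):
        return list(self.W.columns)

    def env_matrix(self) -> pd.DataFrame:
        """The E matrix: elevation, climate, vegetation type."""
        return self.env[["elevation", "temperature", "humidity", "wind",
                         "radiation", "vegetation"]]


def _assign_archetypes(rng, n_species, systems):
    keys = list(ARCHETYPE_FREQS)
    probs = np.array([ARCHETYPE_FREQS[k] for k in keys])
    probs = probs / probs.sum()
    idx = rng.choice(len(keys), size=n_species, p=probs)
    colors = [keys[i][0] for i in idx]
    uv = [keys[i][1] for i in idx]
    # hummingbird-pollinated flowers skew red UV-absorbing
    for i, syst in enumerate(systems):
        if syst == "hummingbird" and rng.random() < 0.7:
            colors[i], uv[i] = "red", "UV-absorbing"
    return colors, uv


def gen_community(config: SimConfig) -> SyntheticCommunity:
    """Generate the full dataset for one seed (see module docstring)."""
    ss = np.random.SeedSequence(config.seed)
    r_tree, r_trait, r_env, r_asm, r_spec, r_label = [
        np.random.default_rng(s) for s in ss.spawn(6)]
    S = config.n_species

    # phylogeny + Brownian latent color traits
    tree_seed = int(ss.generate_state(1)[0] % (2**31 - 1))
    tree = simulate_pure_birth(S, birth_rate=1.0, seed=tree_seed)
    P = cophenetic_distances(tree)
    species = list(P.index)
    n_traits = config.n_latent_traits
    traits_num = pd.DataFrame(
        {f"trait{k + 1}": simulate_bm(tree, sigma2=1.0,
                                      seed=int(r_trait.integers(2**31 - 1)))
         for k in range(n_traits)}).loc[species]

    # pollination systems
    systems = r_label.choice(list(config.pollination_mix),
                             p=list(config.pollination_mix.values()), size=S)

    # plot design: sites x transects x plots, elevation + climate
    lo, hi = config.elevation_range
    site_elev = np.linspace(lo, hi, config.n_sites)
    rows = []
    plots_per_transect = config.plots_per_site // config.transects_per_site
    for si in range(config.n_sites):
        for tr in range(config.transects_per_site):
            t_off = r_env.normal(0.0, 10.0)
            for pl in range(plots_per_transect):
                elev = site_elev[si] + t_off + r_env.normal(0.0, 5.0)
                veg = ("CE" if elev < 900
                       else VEGETATION_TYPES[1:][r_env.integers(4)])
                rows.append({
                    "plot": f"s{si + 1}t{tr + 1}p{pl + 1}",
                    "site": f"site{si + 1}",
                    "transect": f"s{si + 1}t{tr + 1}",
                    "elevation": elev,
                    "vegetation": veg,
                    "temperature": 25.0 - 0.0065 * (elev - lo) + r_env.normal(0, 0.4),
                    "humidity": 60.0 + 0.02 * (elev - lo) + r_env.normal(0, 1.5),
                    "wind": 2.0 + 0.003 * (elev - lo) + r_env.normal(0, 0.15),
                    "radiation": 850.0 + 0.15 * (elev - lo) + r_env.normal(0, 12.0),
                })
    env = pd.DataFrame(rows).set_index("plot")
    n_plots = len(env)

    # assembly: species envelopes / weights per mode
    t1 = traits_num["trait1"].to_numpy()
    t1_rank = (pd.Series(t1).rank(method="average").to_numpy() - 0.5) / S
    elev_p = env["elevation"].to_numpy()
    g = (elev_p - lo) / (hi - lo)  # gradient position in [0, 1]
    eff = config.effect_size
    if config.assembly_mode == "neutral":
        centers = r_asm.uniform(lo - 100.0, hi + 100.0, size=S)
        weights = np.exp(-((elev_p[:, None] - centers[None, :]) ** 2)
                         / (2.0 * config.envelope_sd ** 2))
    elif config.assembly_mode == "convergent":
        # environmental filtering: occurrence envelope tracks trait1
        centers = lo + t1_rank * (hi - lo) + r_asm.normal(
            0.0, 30.0 + (1.0 - eff) * 300.0, size=S)
        sd = 80.0 + (1.0 - eff) * 150.0
        weights = np.exp(-((elev_p[:, None] - centers[None, :]) ** 2)
                         / (2.0 * sd ** 2))
    else:
        # divergent: within-plot spread in trait1 grows with elevation at a
        # constant mean (variance gradient, the divergence signature); the
        # two tails get equal probability mass so no mean (convergence)
        # gradient leaks in
        med = np.median(t1)
        dev = np.abs(t1 - med)
        u = (pd.Series(dev).rank(method="average").to_numpy() - 0.5) / S
        tau = 0.30 - 0.15 * eff
        weights = np.exp(-((u[None, :] - g[:, None]) ** 2) / (2.0 * tau ** 2))
        weights = weights + 1e-9
        upper = t1 >= med
        for p in range(weights.shape[0]):
            w = weights[p]
            w[upper] *= 0.5 / w[upper].sum()
            w[~upper] *= 0.5 / w[~upper].sum()
    weights = weights + 1e-9

    W = np.zeros((n_plots, S), dtype=np.int8)
    max_rich = min(S - 1, 12)
    for p in range(n_plots):
        k = int(np.clip(r_asm.poisson(config.mean_richness), 2, max_rich))
        pr = weights[p] / weights[p].sum()
        chosen = r_asm.choice(S, size=k, replace=False, p=pr)
        W[p, chosen] = 1
    # guarantee every species occurs at least once (keeps the swap null sane)
    for s in range(S):
        if W[:, s].sum() == 0:
            W[r_asm.integers(n_plots), s] = 1
    W = pd.DataFrame(W, index=env.index, columns=species)

    # categorical labels + spectra
    colors, uv_classes = _assign_archetypes(r_label, S, systems)
    uv_pattern = r_label.random(S) < config.uv_pattern_fraction
    mimicry = r_label.random(S) < 0.32
    guides = r_label.random(S) < 0.13
    has_pattern = uv_pattern | mimicry | guides

    spectra = SpectrumSet()
    for i, sp in enumerate(species):
        center_uv = uv_classes[i]
        if uv_pattern[i]:
            center_uv = ("UV-absorbing" if uv_classes[i] == "UV-reflecting"
                         else "UV-reflecting")
        for rep in range(config.n_flower_replicates):
            peri, cent = gen_flower_spectrum(colors[i], uv_classes[i], r_spec,
                                             noise_sd=config.noise_sd,
                                             center_uv_class=center_uv)
            spectra.add(sp, "flower_periphery", str(rep + 1), peri)
            spectra.add(sp, "flower_center", str(rep + 1), cent)
        for rep in range(config.n_leaf_replicates):
            spectra.add(sp, "leaf", str(rep + 1), gen_leaf_spectrum(
                r_spec, noise_sd=config.noise_sd))

    traits = traits_num.copy()
    traits.insert(0, "human_color", colors)
    traits.insert(1, "uv_class", uv_classes)
    traits.insert(2, "pollination_system", systems)
    traits["has_pattern"] = has_pattern
    traits["floral_guide"] = guides
    traits["pollen_anther_mimicry"] = mimicry
    traits["uv_pattern"] = uv_pattern
    traits.index = species
    traits.index.name = "species"

    return SyntheticCommunity(config=config, W=W, env=env, traits=traits,
                              tree=tree, P=P, spectra=spectra)
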