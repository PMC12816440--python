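# Methods

This note documents the models, parameter choices and numerical decisions
behind `chromacomm`, and what the synthetic-data generator does and does
not emulate.

## Spectral processing

Reflectance curves are linearly interpolated onto a uniform working grid,
by default 300–700 nm at 1-nm steps — the window spanned by bee and avian
photoreceptors; field spectrometers usually record a wider range, which is
simply cropped. Reflectance more negative than −0.05 is rejected as a data
error; values in (−0.05, 0) are treated as instrument noise and clipped to
0 with a logged warning. A species' flower color is the pointwise
arithmetic mean of its replicate curves (no outlier rejection); the
adapting background is the grand mean of all leaf curves. Optional boxcar
smoothing (5-nm window) is off by default.

## Receptor models

Receptor sensitivities are Govardovskii A1 nomogram templates (alpha band
plus beta band), peak-normalized, with configurable λmax. Defaults: bee
trichromat UV/blue/green = 328/428/536 nm (bumblebee-type); bird UVS
tetrachromat UV/S/M/L = 355/450/540/605 nm with the double cone given the
L template. The ambient light is the CIE D65 daylight (bundled 10-nm
table, interpolated, normalized to 1 at 560 nm). Quantum catches are
trapezoidal integrals of reflectance × sensitivity × illuminant; chromatic
adaptation is the von Kries division by the background catches, which
makes all downstream quantities invariant to the illuminant's absolute
scale. Ocular-media corrections are not modelled.

Default Weber fractions: bee (0.13, 0.06, 0.12); bird neural-noise regime
with relative cone abundances u:s:m:l = 1:2:2:4 and e_L = 0.1, giving
e_i = 0.1·√(n_L/n_i); double cone e = 0.2. These are the conventional
literature values and are configurable per run.

## Bee color hexagon

Excitation is E = q/(q+1), so the background sits at E = 0.5 per receptor
and at the origin of the hexagon (x = (√3/2)(E_g − E_uv),
y = E_b − (E_uv + E_g)/2). Chromatic contrast is Euclidean distance in
hexagon units (HU); green (achromatic) contrast is |E_g − 0.5|; brightness
defaults to the sum of the three relative catches (a `mean_reflectance`
switch is provided — the choice between the two conventions is genuinely
open). The spectrum locus used for dominant wavelength and spectral purity
is built from narrowband Gaussian stimuli (FWHM 10 nm, peak 1) against the
same background and illuminant, tabulated every 1 nm over 300–550 nm (bee
spectrum loci conventionally end near 550 nm). Dominant wavelength is the
locus entry with the nearest hue angle; stimuli whose hue falls in the
angular gap between the locus endpoints are flagged `purple-line` (bee
purple = UV + green mixture); loci with radius < 0.05 HU are
`achromatic`, with hue, purity and category undefined. Spectral purity is
r(stimulus)/r(narrowband at the dominant wavelength), capped at 1. Color
categories are the six 60° hexagon sectors centered on the three receptor
vertices and their midpoints; angles are measured from the +y (blue)
vertex, and boundary angles are assigned to the counter-clockwise sector.

## Avian tetrahedral model

Relative catches are normalized to proportions and mapped into the regular
tetrahedron with circumradius 0.75, UV vertex on +z and the S/M/L vertices
at z = −0.25, azimuths 90°/210°/330°; equal catches sit at the origin.
Spectral purity is achieved chroma r/r_max along the locus direction
(ray–face intersection). Discriminability is the receptor-noise-limited
model in its general n-receptor form with log receptor signals
Δf_i = ln(qA_i/qB_i):

ΔS² = Σ_{i<j} (Π_{k∉{i,j}} e_k)² (Δf_i − Δf_j)² / Σ_i (Π_{k≠i} e_k)²,

which reduces exactly to the published trichromat closed form (verified in
tests). Achromatic contrast is |ln(qA/qB)|/e on the double cone. Pairwise
flower–flower discriminability summaries use the chromatic ΔS in JND
against the 0.1-JND threshold; bee summaries use hexagon distance against
0.2 HU. (Some studies instead report Euclidean distances within the
tetrahedron; the receptor-noise contrast is used here because it carries
the JND unit the threshold refers to.)

## Categorical traits and association tests

A flower part is UV-reflecting when its mean reflectance over 300–400 nm
is ≥ 0.10 (documented, configurable; the boundary counts as reflecting);
a UV pattern is a periphery/center pair in different UV classes, and a
missing center yields `unknown`, not `false`. Human color names, floral
guides and mimicry flags are observer inputs. The color × pollination-
system association is tested with a G-test (G = 2ΣO·ln(O/E), χ² reference)
and a simple correspondence analysis — SVD of the standardized-residual
matrix, per-axis principal inertias summing to χ²/N — with a permutation
p-value obtained by shuffling the pollination-system labels of the
underlying records (999 by default). A constrained mode (projecting row
profiles onto an external predictor space before the decomposition) is
provided; the unconstrained analysis is the default because the constrained
design is under-determined for this table.

## Community diversity and the null model

Trait distances among species are mixed-type Gower distances (numeric:
|Δ|/range; categorical: 0/1; pairwise deletion of missing traits; constant
traits dropped). Per plot, MPD and MNTD are computed on presence/absence
(abundance weighting is deliberately out of scope). The null model is the
independent swap — 2×2 checkerboard swaps preserving plot richness and
species frequency exactly — run as a Markov chain; `n_swaps` counts
*attempted* picks so runtime is bounded on sparse matrices. Defaults:
burn-in max(10 000, 50·n_plots) and thinning max(1 000, 5·n_plots)
attempts; the floors match the study-scale design (≤200 plots) and the
scaling keeps the chain comparably mixed on larger matrices (without it, a
1000-plot calibration run showed sd(z) ≈ 1.08 and type-I error 0.069
instead of ≈1.02/0.056). SES is z = (obs − null mean)/null sd over 999
samples with a two-sided empirical p using the +1 correction,
p = 2·min(r+1, n−r+1)/(n+1). Plots with fewer than two species are
excluded and listed. The front end is `ColorDiversityModel(W, D,
metadata).fit()`.

## Assembly framework

`TraitAssemblyModel(W, B, E, P).fit()` runs the seven-test battery on
min–max standardized numeric traits and environment (vegetation type
expanded to 0/1 indicators before standardization):

1. **Trait convergence (TCAP)** — ρ(TE): Pearson correlation between
   plot-pairwise Euclidean distances of T = community-weighted means and
   of E.
2. **Trait divergence (TDAP)** — ρ(XE·T): partial correlation between the
   distances of X and E given T, where X = W·U row-normalized and
   U = 1 − Gower(B) column-normalized (the trait-similarity-weighted
   composition).
3.–5. **Phylogenetic structure** — the same correlations computed on the
   phylogenetically weighted composition X_P = W·Q (Q = column-normalized
   1 − P/max P, rows of X_P normalized), against E, T and X.
6.–7. **Removing phylogeny** — TCAP/TDAP re-run on trait residuals from
   the principal coordinates of P (axes covering 95% of the positive
   eigenvalue trace; traits collapsing to zero residual are dropped).

Tests 1, 2, 6, 7 draw their null by permuting species rows of B (U and T
rebuilt per draw); tests 3–5 shuffle the tips of P. Each null breaks
exactly the linkage under test; p-values are one-sided (≥) with the +1
correction, 1000 permutations by default. Degenerate statistics
(zero-variance distance vectors, |r| = 1 in the partial) are flagged NA
rather than forced. The X/Q constructions above are fixed as this
package's canonical variant of the framework so results are reproducible.

Trait selection fits one OLS per trait (CWM on plot elevation; direction
reported only when p < 0.05) and marks as "selected" the traits that are
both regression-significant and members of the trait subset maximizing
the observed ρ(TE) — exhaustive search up to 12 traits, greedy forward
beyond, ties broken toward fewer traits.

## Phylogenetic signal

Blomberg's K is the ratio of observed MSE₀/MSE (phylogenetically
estimated mean; MSE under the Brownian covariance C implied by the tree)
to its Brownian expectation (tr C − n/Σ C⁻¹)/(n − 1). The quadratic form
is evaluated in Cholesky-whitened form with a 1e-10-relative jitter so it
stays nonnegative on trees with near-duplicate tips. Significance is a
tip-shuffle permutation test (one-sided, +1 correction, 999 default).
K ≈ 1 is the Brownian expectation, K > 1 stronger-than-Brownian
resemblance, K < 1 overdispersion — output notes state this standard
reading explicitly because a contrary phrasing ("K around 1 = no signal")
circulates. Pure-birth tree simulation delegates to dendropy and then
extends every extant tip by the Exp(nλ) waiting time to the next,
unrealized, speciation — the simulator otherwise stops exactly at the
n-th birth, leaving zero-length terminal branches that degenerate the
covariance. Brownian traits are simulated edge-by-edge.

## Regression layer

OLS and the random-intercept linear mixed model go through statsmodels
(REML for the LMM); this package adds the Nakagawa–Schielzeth
decomposition — marginal R² = var(fixed)/(var(fixed) + var(group) +
var(resid)), conditional R² adds var(group) to the numerator — and the
Table-style output (Term, Estimate, Error, t, P, marginal and conditional
R²). Conditional ≥ marginal holds by construction and is asserted. A
single-group input falls back to OLS with a warning. p-values are
unadjusted Wald tests.

## Synthetic-data generator

The generator emulates the study design the analyses assume: 5 sites × 36
1-m² plots (four transects of 9), elevations spanning 808–1427 m with
transect-level jitter, 179 species, pollination mix 75% bee / 8%
hummingbird / 17% other, vegetation types CE below 900 m and RO/SA/ST/WE
above, and climate columns (temperature decreasing, humidity/wind/
radiation increasing with elevation, plus noise). Flower spectra are
archetypes — logistic long-pass edges and/or Gaussian bumps per human
color (pink, white, whitish, yellow, red, green), blended below 400 nm
into a UV band at 0.20 (UV-reflecting) or 0.02 (UV-absorbing), with
multiplicative lognormal noise (σ = 0.05) and 10 replicates per species;
archetype frequencies follow the inventory led by pink UV-absorbing
(28%), white UV-absorbing (18%) and yellow UV-reflecting (17%). The
archetype constants aim at qualitative fidelity only (e.g. yellow
UV-reflecting lands in the bee uv-green sector, red UV-absorbing is
UV-dark); they are not fitted to any measured flora. Centers flip UV
class for the 23% of species given UV patterns. Leaves are green-peaked
(max near 550 nm) with a near-infrared shoulder starting at ~697 nm.

The phylogeny is a pure-birth tree; the latent trait table holds two
Brownian traits (σ² = 1): `trait1` is the gradient-responsive trait the
assembly modes act on, `trait2` is neutral. Two traits keep the planted
signal from being diluted away in the Gower/CWM averaging — the
convention in recovery simulations of this framework, which typically use
one to three traits. Community assembly per plot draws a Poisson(8)
richness (clipped to [2, 12]) and samples species without replacement:

* **neutral** — Gaussian elevation envelopes (σ = 150 m) with centers
  independent of traits;
* **convergent** — envelope centers track the rank of `trait1` across the
  gradient (noise sd 30 m at effect 1, envelope σ = 80 m): classic
  optimum-tracking environmental filtering, detected by TCAP;
* **divergent** — within-plot spread in `trait1` grows with elevation at
  constant mean: sampling weight is a Gaussian ring over the rank of
  |trait1 − median| centered at the plot's gradient position (width
  τ = 0.30 − 0.15·effect, i.e. 0.15 at the default effect 1), with the
  two tails given equal probability mass so no mean (convergence)
  gradient leaks in. This variance-along-the-gradient construction is the
  signature TDAP is built to detect.

All randomness derives from one seed through spawned generator streams,
so any component can be re-generated independently and identically.

What the generator does **not** emulate: spatial autocorrelation between
neighboring plots, abundance structure, measurement geometry of real
spectrometers, phenology, or any fit to the deposited field data. Passing
calibration/recovery tests therefore demonstrates internal statistical
correctness of the pipeline under its stated assumptions, not that real
campo rupestre communities behave this way.

## Problem sizes used in the test batteries

The calibration and power batteries run on reduced communities (5 sites ×
12 plots, 40 species, 3 spectral replicates): neutral calibration with
500 replicates at 199 permutations, power batteries with 100 replicates,
SES calibration on 200- and 1000-plot null-drawn matrices with 999
randomizations, phylogenetic-signal batteries with 200 replicates of
64-tip (power) and 32-tip (calibration) trees, and 200 mixed-model
recovery replicates. These sizes give binomial standard errors of about
0.01–0.03 on the reported rates. `scripts/acceptance.py` re-runs the same
batteries at 60–100 replicates.

## Known limitations

* Dominant wavelength is resolved to the 1-nm spectrum-locus grid; hue
  angles within ~0.5° of a sector boundary can flip category under
  different λmax choices.
* The receptor-noise model assumes the Weber (neural-noise) regime;
  photon-noise-limited conditions (dim light) are out of scope, as are
  violet-sensitive (VS) avian systems.
* The correspondence analysis permutation test treats table counts as
  independent records; weighted (record-level) tables with non-integer
  weights are rounded for the permutation step.
* The LMM reports Wald p-values with the default statsmodels df; no
  Kenward–Roger or Satterthwaite correction.
* Megaphylogeny pruning is out of scope: users supply a pruned Newick
  whose tips match the trait table.
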