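# Methods

This note documents the models, defaults and design choices behind
`pamdsi`, in the spirit of a statistical-software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Quenching analysis

The package implements the standard saturation-pulse quenching analysis
of PAM fluorometry. A dark-adapted leaf supplies the minimal/maximal
pair (F₀, Fₘ); each actinic step supplies steady-state F_s and the
pulse maximum Fₘ′. Derived quantities:

| quantity | formula | units |
|---|---|---|
| F_v/Fₘ | (Fₘ − F₀)/Fₘ | — |
| Y(II) | (Fₘ′ − F_s)/Fₘ′ | — |
| Y(NPQ) | F_s/Fₘ′ − F_s/Fₘ | — |
| Y(NO) | F_s/Fₘ | — |
| qP | (Fₘ′ − F_s)/(Fₘ′ − F₀′) | — |
| qL | qP · F₀′/F_s | — |
| qN | 1 − (Fₘ′ − F₀′)/(Fₘ − F₀) | — |
| NPQ | (Fₘ − Fₘ′)/Fₘ′ | — |
| ETR | Y(II) · PAR · 0.5 · 0.84 | µmol e⁻ m⁻² s⁻¹ |

Choices worth noting:

- **F₀′** is rarely measured by imaging protocols, so it is estimated
  with the Oxborough–Baker formula F₀′ = F₀/(F_v/Fₘ + F₀/Fₘ′) by
  default; a measured column overrides it. The estimator guarantees
  F₀′ ≤ F₀ and F₀′ < Fₘ′, and (provably, via the monotonicity of
  Fₘ′ − F₀′ in Fₘ′) keeps qN within [0, 1] for any valid reading —
  a property the test suite checks over random inputs.
- **NPQ, qN, qL** use the Bilger–Björkman, classical and lake-model
  definitions respectively; these are what Imaging-PAM software reports.
- ΔF ≡ Fₘ′ − F_s, and the "F" of the qP formula is read as F_s.
- **qP and qL are clamped to [0, 1]** after floating-point noise (the
  dark limit F_s = F₀′ makes both exactly 1); a qP excursion beyond
  1 × 10⁻⁶ additionally raises a data-quality warning, since it implies
  an F_s below F₀′ — inconsistent readings rather than rounding.
- The three quantum yields satisfy Y(II)+Y(NPQ)+Y(NO) = 1 to machine
  epsilon by construction; the ETR constants 0.5 (photosystem
  stoichiometry) and 0.84 (leaf absorptance) are the conventional
  higher-plant values.

All parameters except ETR are ratios of fluorescence in arbitrary
units, hence invariant to rescaling the raw signal (property-tested).

## Rapid light curves

ETR vs PAR curves over the instrument ramp
(0, 1, 21, 56, 111, 186, 281, 336, 396, 461, 531, 611, 701 µmol
photons m⁻² s⁻¹ — thirteen levels) are summarised two ways:

- **empirical rule**: ETR_max = highest observed ETR; α = least-squares
  slope through the origin over the first three nonzero-PAR points;
  E_k = ETR_max/α. This mirrors instrument practice but necessarily
  underestimates the asymptote of a saturating response.
- **tanh fit**: nonlinear least squares on
  ETR = ETR_max·tanh(α·PAR/ETR_max), initialised from the empirical
  summary, positivity-bounded, convergence tolerances 10⁻¹⁰. On
  noise-free curves the fit recovers generating parameters to ~0.1%;
  non-convergence returns the empirical values flagged
  `converged=False`.

E_k = ETR_max/α is the saturation-onset irradiance implied by the tanh
model (the model names no E_k of its own). E_k·α = ETR_max holds
exactly for every returned fit. No photoinhibition term (Platt β), dark
respiration rate or light compensation point is estimated; the
measurement protocol modelled here does not determine them.

## Disease susceptibility index

For each season, per variable *v* and genotype *j*, genotype ×
condition means Y_{jvc} (c ∈ {healthy HL, infected AL}) are computed by
arithmetic averaging over blocks/plants/leaves/leaflets/AOIs. Then:

1. **Standardize**: pool HL and AL values of *v*, divide by the
   geometric mean of the pooled vector, min-max rescale to [0, 1].
   Pooling keeps both conditions on one scale so the infection drop
   survives; scaling each condition separately would erase precisely
   the largest drops. The geometric-mean ratio is affine-equivalent to
   the raw values and therefore a no-op under the following min-max;
   it is retained for fidelity to the published construction and
   asserted as a no-op in the tests.
2. **Orient**: damage-signature variables (F₀, qN, Y(NPQ), Y(NO) by
   default) are reflected (x → 1 − x) so "larger = better" holds
   everywhere. NPQ's role is genuinely ambiguous — it can rise as
   photoprotection or fall with loss of chloroplast function — so NPQ
   defaults to more-is-better with a configuration switch.
3. **Sub-indices**: SI₁ = max_j′ HL_{j′v} − HL_{jv} (healthy-performance
   deficit, ≥ 0, zero for the best genotype); SI₂ = HL_{jv} − AL_{jv}
   (infection drop; negative values are allowed and kept).
4. **Aggregate**: raw_j = Σ_v (SI₁ + SI₂); per-season DSI = min-max of
   raw over genotypes (best genotype 0, worst 1); pooled DSI = mean of
   seasonal indices, which absorbs season-to-season disease pressure.

The default variable set is the ten dark/light summaries (F₀, Fₘ,
F_v/Fₘ, Y(II), Y(NPQ), Y(NO), NPQ, qN, qP, qL; light-adapted ones
averaged over PAR > 0 steps) plus ETR at every PAR level — 23
variables with the standard ramp. ETR at PAR = 0 is identically zero;
constant variables are detected before the positivity check and
standardized to all zeros with a warning, contributing nothing, rather
than failing the geometric mean. A constant raw score (e.g. a single
genotype) degenerates to DSI = 0 with a warning. "Max" in SI₁ is taken
within season.

## Typologies and statistics

- **Features**: by default, the pooled DSI plus each summary variable's
  healthy-minus-infected drop (and ETR@281's drop), z-scored.
  Susceptibility typologies are defined by infection *response*;
  absolute levels carry genotype background that blurs adjacent classes
  (and in published class tables adjacent classes overlap on most level
  variables). Levels can be added with `include_levels=True`.
- **Clustering**: Ward linkage on Euclidean distances, cut at k = 4;
  clusters are labelled MR/MS/S/HS by ascending mean DSI, ties broken
  by descending size with a warning.
- **PCA** is an eigendecomposition of the feature correlation matrix;
  "loadings" are the orthonormal eigenvectors, variable contributions
  are squared loadings normalized to 100% per axis, and the reference
  threshold is 100/p (the expected contribution if all p variables
  mattered equally). Constant features are dropped with a warning.
- **Permutation test**: the statistic is the between-class share of
  total inertia (sum of squares) in feature space, in [0, 1]; class
  labels are permuted (999 by default, seeded) and
  p = (1 + #{permuted ≥ observed})/(n + 1), so the smallest attainable
  p is 1/(n+1) and the test is exact-level by construction. The test's
  null rejection rate is verified by Monte-Carlo calibration in the
  acceptance suite.
- **Fisher LSD**: one-way ANOVA pooled MSE, pairwise comparisons at
  α = 0.05, compact letter display built from the maximal cliques of
  the not-significantly-different graph, ordered by descending mean —
  a deterministic function of (means, MSE, group sizes, α). The
  original repeated-measures structure is collapsed to block-level
  means before group comparisons; no mixed model is fitted.
- **Pearson matrices** use pairwise-complete observations, two-sided
  t-tests, stars at 0.05/0.01/0.001, NaN for constant variables.

## Synthetic trial generator

No raw data accompany the field study the pipeline targets, so
`pamdsi.synthgen` generates panels with the study's hierarchical design
(2 seasons × 3 blocks × 59 genotypes × 4 plants × 4 leaves × 3 leaflets
× 2 AOIs × 2 conditions; 5664 AOI units per condition per block per
season) and its qualitative infection contrasts.

**Mechanism.** Each genotype draws latent healthy-leaf parameters from
its class population: tanh light-response (ETR_max, α), F_v/Fₘ, and an
NPQ capacity with saturating trajectory NPQ(PAR) =
cap·(1 − e^(−PAR/250)). Raw readings are constructed by inversion:
Y(II) = ETR/(0.42·PAR) from the tanh curve (F_v/Fₘ at PAR 0), then
Fₘ′ = Fₘ/(1+NPQ) and F_s = Fₘ′(1 − Y(II)), which guarantees
0 < F_s ≤ Fₘ′ ≤ Fₘ and exact internal consistency of every derived
parameter. Y(II) is additionally capped at 99% of the photochemical
ceiling 1 − F₀′/Fₘ′ so qP stays within [0, 1] even for severely
diseased leaves.

**Infection.** A single latent severity d per genotype (jittered,
clipped to [0.02, 0.92]) scales every infected-leaf shift:
F₀ × (1 + 0.88·d), Fₘ × (1 − 0.455·d), ETR_max × (1 − d),
α × (1 − 0.5·d), NPQ capacity × (1 − 0.2·d). The F₀/Fₘ coefficients
reproduce, at the default panel's mean severity (d ≈ 0.44), the field
contrasts of ~+39% F₀ in infected and ~+25% Fₘ in healthy leaves; the
NPQ coefficient is chosen by algebra so NPQ falls under infection while
the derived qN still rises, and elevated Y(NO) follows automatically
from Y(NO) = (1 − Y(II))/(1 + NPQ). These are generator defaults, not
validated claims about any real pathosystem.

**Classes.** Default class sizes 6/16/29/8 (MR/MS/S/HS; other panel
sizes are allocated by largest remainder); class latents anchor
ETR_max/E_k at 65.66/458.1, 49.40/365.31, 46.84/358.17, 19.71/163.0,
F_v/Fₘ at 0.80/0.79/0.78/0.76 (all below the 0.82 unstressed
threshold), NPQ capacity 1.2/1.1/1.0/0.9, severity 0.10/0.30/0.50/0.75.
Seasons differ by a single multiplicative severity factor (0.9/1.1 for
two seasons). Noise is multiplicative lognormal at genotype (CV 8% on
ETR_max), plant (6%), leaf (4%) and AOI (3%) levels, additive on F_v/Fₘ
(SD 0.015) and severity (SD 0.04); no variance components are published
for the design, so these are free parameters set at scales consistent
with the published class standard errors.

**What the generator does not emulate** — and hence what passing tests
cannot show about real data: pathogen biology and lesion growth,
weather, block × genotype interactions, spatial field structure,
instrument saturation-pulse inadequacy, or the empirical F₀
class-level pattern (the generator ties F₀ strictly to severity;
field data show class differences in dark-adapted F₀ beyond that).
Tests on synthetic panels validate the *pipeline's* algebra, ordering
behaviour and statistical calibration, not field biology.

**Images.** Parameter maps are rendered at the camera resolution
(480 × 640) with AOI circles (default radius 15 px; the instrument's
AOI radius is not published), Gaussian pixel noise, and a
`lesion_fraction` of AOI pixels set to exactly 0 — matching black
necrotic patches. Necrosis masking flags pixels below 2% of the
99th percentile of the reference channel's positive pixels (restricting
to positive pixels keeps a large zero background from collapsing the
threshold); a fully masked AOI reports missing, never 0.

## Problem sizes and numerical choices

The default test run generates full-design panels (≈ 884k reading rows
each) for five seeds in the typology-recovery check, 200 replicate
noisy light-curve fits, and 400 replicate null datasets × 199
permutations for permutation-test calibration; the whole suite runs in
a few minutes on one CPU. Degenerate inputs are contracts, not crashes:
all-zero light curves warn and fall back, constant variables warn and
drop (or standardize to zero), single-genotype DSI warns and returns 0,
fully necrotic AOIs report missing values. All randomness flows from
explicit integer seeds; identical seeds give byte-identical tables.
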