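# Methods

## The scientific question and the model

A brain nucleus that "grows" under a hormonal stimulus can do so in two
fundamentally different ways: the tissue can physically expand (cells move
apart), or the *detectable* boundary can move while the cellular scaffold
stays put (cells at the margin change phenotype). Longitudinal imaging of
the same labelled neurons distinguishes the two, because physical expansion
makes a hard geometric prediction while boundary re-delineation predicts
nothing about cell positions.

`hvctrack` formalises the expansion hypothesis as uniform isotropic scaling.
The nucleus is idealised as a cube of side L₀ (default 500 µm, volume
V₀ = L₀³ = 0.125 mm³). A volume increase of p percent gives
V′ = V₀·(1 + p/100) and, under uniform linear scaling, L′ = L₀·s with
s = (1 + p/100)^(1/3). Cell coordinates transform as
x′ = c + s·(x − c) about a center c. Two statistics follow:

- **Per-point displacement** ‖x′ − x‖ = (s − 1)·‖x − c‖. This depends on
  the choice of c. For points uniform in the cube and c at the cube center,
  mean = (s − 1)·c₁·L₀ and SD = (s − 1)·c₂·L₀, where c₁ = E‖U‖ =
  0.4802959782… (U uniform on the unit cube centered at 0; computed by
  adaptive quadrature to <1e−12 absolute error) and
  c₂ = sqrt(1/4 − c₁²) = 0.1389811976… (E‖U‖² = 1/4 exactly). At L₀ =
  500 µm this gives 3.94 ± 1.14 µm for p = 5%, 15.05 ± 4.35 for 20%,
  34.75 ± 10.06 for 50% and 57.29 ± 16.58 for 90%.
- **Pairwise distance change** D′ − D₀ = (s − 1)·D₀ for every pair,
  *independent of the center* — the reason pairwise distances are the
  preferred observable. For uniform points the mean is (s − 1)·R·L₀ with
  R = 0.6617071823… the mean distance between two uniform points in the
  unit cube (Robbins constant, closed form).

Per-point displacements are center-dependent; the package defaults to
scaling about the cube center (the choice that reproduces the closed forms
above), with `origin_corner` and `centroid` modes available. The Monte
Carlo simulator (`simulate_expansion`) draws fresh uniform clouds per
replicate and pools both statistics; tests require agreement with the
closed forms within 3 standard errors.

Model inversion (`estimate_expansion`) uses
ŝ = 1 + mean(D′ − D₀)/mean(D₀), p̂ = (ŝ³ − 1)·100, which is exact under
pure scaling and unbiased to first order under zero-mean localisation
noise.

## Testing observed tracks against a model

For a bird imaged at days a and b, pairs are formed from neurons present in
both sessions (matched by label; missing neurons are counted as dropout,
never imputed) and the delta vector D′ − D₀ is computed over all pairs.

The statistically delicate point is that pairwise deltas are *not*
independent: two pairs sharing a neuron share that neuron's localisation
error, and the mean delta is a U-statistic whose variance is roughly
4·ζ₁/k (k neurons), not s²/n_pairs. Treating the deltas as i.i.d. produces
a wildly anticonservative test — in simulation, a nominal 5% test rejected
the true model ~65–68% of the time, and per-neuron pre-averaging still
rejected ~28%. The package therefore tests a model p by forming the
pair-matched residuals (D′ − D₀) − (s − 1)·D₀ and estimating the standard
error of their mean with a **leave-one-neuron-out jackknife** (delete all
pairs touching one neuron, recompute the mean, k pseudo-values), with
df = k − 1. In simulation this test rejects the true model at 5/100 at
α = 0.05 and the wrong model (0% vs true 10%, or vice versa) at 100/100
with 44 neurons — the smallest cohort size of interest. Residuals that
vanish to floating-point precision (an exactly matching model) short-cut
to t = 0, p = 1.

The ANOVA-with-Tukey comparison of the observed delta distribution against
one simulated realisation of the model's delta distribution is also
computed for every grid cell and reported alongside (F, df, signed
q = (mean_measured − mean_model)/SE; positive q means the constellation
changed more than the model predicts). It is the familiar group-level
description, but because it ignores the pair-dependence structure its
p-values are not calibrated; significance counts in reports always come
from the jackknife matched test.

Per-bird day-pair summaries (mean ± SD of deltas) feed an OLS trend of
mean shift against the later session day; R² of a zero-variance response
is defined as 0. Birds are never pooled before testing — the pooled
mean ± SD across birds (pair-count weighted) is descriptive only.

## Comparison layer

F, t and q are computed from classical sums of squares; p-values come from
the scipy F, t and studentized-range distributions. Conventions:

- Tukey SE is the Tukey–Kramer form sqrt(MS_within·(1/n_a + 1/n_b)/2); an
  alternative `sum_of_means` convention, sqrt(s_a²/n_a + s_b²/n_b), is
  available behind a flag but is not exactly studentized-range distributed.
  The conventional form is the default because it is the one with
  calibrated p-values.
- Two-sample t is pooled-variance by default (df = n_a + n_b − 2, matching
  designs reported via printed summaries); Welch is available.
- Two-way ANOVA fits value ~ C(factor_a) + C(factor_b) by OLS with
  sequential (type I) sums of squares, factor_a first, no interaction term.
  Degenerate exact fits (MS_resid = 0) report F = 0 for a null effect and
  F = ∞ otherwise.
- An all-constant comparison (zero variance between and within) is an
  error for the generic tests; the area-ratio test catches it and reports
  t = 0, p = 0.5, since identical delineations carry no evidence either
  way.

## Volumetry and morphometry

Cavalieri estimation: with sections of thickness t µm and every k-th
section sampled, spacing = t·k and V = Σ areas × (t·k·10⁻³) mm³. The
wording "area times thickness times distance between sections" is read as
area × (thickness × sampling step) — the standard estimator; a literal
double multiplication would be dimensionally wrong. Defaults t = 20 µm,
k = 5 (spacing 100 µm). The estimator is exact for constant-area slabs and
invariant to zero-area padding.

Group volumes are compared with a one-sided pooled t (treated > control).
Delineation ratios (molecular/Nissl vs molecular/traced) are compared
within each group by an unpaired one-sided pooled t, df = 2(n − 1) — at
n = 3 per side, df = 4.

Morphometry: bouton density is count/length per branch and session; stage
windows are half-open on integer days, [lo, hi + 1), with a boundary day
assigned to the later window. Defaults: song onset DPI 1–10 vs full song
DPI 30–42 for boutons; DPI 0 vs DPI 28–42 for soma areas. Stage effects
use the two-way ANOVA with stage and bird as crossed factors, reporting
the stage main effect.

## Synthetic data: what it emulates and what it does not

`gen_tracks` draws true positions uniformly in the 500 µm cube, applies a
scheduled cumulative expansion about the cube center, adds independent
zero-mean Gaussian localisation noise — σ_xy = 0.5 µm, σ_z = 2.0 µm,
anchored to the ~480 nm lateral and ~2,000 nm axial optical resolution of
two-photon imaging — and drops neurons per session at rate 0.1 (cohort
cell counts in real data vary by tens of percent between days). A
`session_jitter` option adds a rigid per-session offset (default 0):
day-to-day scatter in real data (SDs of several µm) plausibly includes
repositioning error beyond pure localisation noise, but rigid offsets
cancel exactly in pairwise distances, so the default conservatively omits
them. `gen_sections` draws per-bird volumes from the group laws
0.206 ± 0.028 mm³ (n = 6, treated) and 0.110 ± 0.036 mm³ (n = 4, control)
and spreads each over a parabolic profile integrating exactly to the drawn
volume. `gen_morphology` keeps soma areas i.i.d. normal at 13.4 ± 2.0 µm²
regardless of stage and makes bouton counts Poisson with a density ramp
0.1 → 0.2 boutons/µm across the recording period.

What the generators do **not** emulate: non-uniform (clustered) neuron
layouts, anisotropic or spatially graded expansion, registration drift,
segmentation errors that mislabel neuron identity, non-Gaussian heavy-tailed
localisation error, and section-to-section area measurement noise. Passing
tests therefore demonstrate correctness of the statistical machinery under
the stated model, not robustness to all failure modes of real imaging data.

## Numerical and design choices

- Geometric constants are frozen at quadrature/closed-form precision
  (c₁ = 0.4802959782275265, c₂ = 0.13898119764365024,
  R = 0.6617071822671762); Monte Carlo agreement is asserted in tests.
- Shrinkage (p < 0) is permitted down to p > −100 only behind an explicit
  `allow_shrink` flag; p ≤ −100 (non-positive volume) is always rejected.
- Sessions' neuron sets intersect before pairing; <2 shared neurons is an
  error, not a silent skip.
- RNG: every stochastic routine takes a seed (or Generator); grids derive
  child seeds via `SeedSequence.spawn`, so reports are bit-reproducible
  given the config seed. CSV writers use `%.17g` and readers parse with
  round-trip precision, making write → read the identity on doubles.
- Default simulation sizes (100-point clouds, 300–1000 replicates, 100-seed
  calibration sweeps) were chosen so that Monte Carlo error is well below
  the 1 µm print precision of the quantities of interest.

## Known limitations

- The matched model test assumes complete pair sets (all k(k−1)/2 pairs of
  the shared neurons); partially observed distance matrices are not
  supported.
- The ANOVA/Tukey grid is reported for comparability but, as noted, its
  p-values ignore pair dependence; use the matched test for inference.
- The expansion model is isotropic and homogeneous by construction;
  rejecting it does not rule out exotic non-uniform growth, only growth
  that preserves shape.
- Area-ratio tests treat birds as unpaired between ratio sets even though
  both ratios come from the same birds; this matches a df = 2(n − 1)
  design and is conservative when the ratios are positively correlated.
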