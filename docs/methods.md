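# Methods

This note documents the models, conventions and design choices behind
`vitespec`, in the spirit of a statistical package's methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## 1. Trait table

Derived traits: WUE_intr = A_max/g_s (µmol CO₂ mol⁻¹ H₂O), WUE_inst =
A_max/E (µmol CO₂ mmol⁻¹ H₂O), LMA = dry mass / area (g m⁻²), LDMC = dry
mass / water-saturated fresh mass (mg g⁻¹). Zero denominators yield missing
cells with a warning — the ratio is undefined, and silently propagating an
infinity would poison downstream summaries.

Summary statistics report mean, SD, median, MAD, min, max, CV and
Shapiro–Wilk W/p (scipy's Royston implementation). Conventions worth making
explicit:

- **MAD is unscaled** (no 1.4826 normal-consistency factor). The choice is
  cosmetic for screening purposes and is not configurable per call — the raw
  median absolute deviation is what the summary table prints.
- **CV uses |mean|**: two traits (Ψ_pd, δ¹³C) are negative-valued and a
  negative CV has no useful reading; 100·sd/|mean| keeps the column
  positive and comparable across traits.
- **Quartiles and quantiles are type-7** (linear interpolation), numpy's
  default, everywhere: the IQR outlier rule, spectra quantile envelopes.

The IQR outlier rule removes cells outside [Q1 − 2·IQR, Q3 + 2·IQR]. Only
individual trait cells are masked, never whole leaves, so per-trait sample
sizes differ downstream; that asymmetry is intentional and carried through
the report (`n_obs` per model row). The rule is monotone in the factor
(larger factor removes a subset), degenerate IQR = 0 keeps only exact
ties, and an infinite factor keeps everything.

Log transforms are an explicit registry rather than an automatic decision
from the normality screen, because a Shapiro p-value alone does not
determine the modelling scale; the default registry logs WUE_inst,
WUE_intr, Area, LDMC and LMA. Natural log is used — the base only rescales
coefficients, never R². Transformed columns are renamed with a `log-`
prefix so report rows are unambiguous about the modelled scale.

## 2. Variance partitioning

The cultivar hierarchy is treated as strictly nested: planting row within
cultivar within grape colour (red/white) within origin class, with row
labels recoded unique per cultivar (row "R1" of two cultivars never pools).
The order is a modelling choice — colour and origin are attributes of the
variety, rows are physical positions — and is configurable through the
`nesting` argument.

Estimation is REML via a mixed model with a random intercept per level
(statsmodels MixedLM, variance-component coding). Two numerical points:

- When variance components sit at the zero boundary the default BFGS
  optimiser often reports non-convergence on a near-flat restricted
  likelihood; the fit is retried with derivative-free Powell, which handles
  the boundary reliably. If both fail, a balanced nested-ANOVA
  expected-mean-squares (method-of-moments) estimator takes over, and the
  result is labelled `moments-fallback`.
- Negative estimates are truncated at zero and proportions renormalised, so
  reported proportions are non-negative and sum to exactly 1.

The moments estimator is also exposed directly (`method="moments"`) and
doubles as an independent cross-check: on balanced one-way designs REML and
the ANOVA estimator agree, which the test suite verifies per dataset.

With only two origin classes and two colours, the top-level variance
estimates are intrinsically noisy; proportion estimates for those levels
should be read as order-of-magnitude indicators.

ANOVA across cultivars is one-way with Tukey HSD post-hoc (all pairwise
cultivar comparisons per trait; no cross-trait multiplicity correction).
For two groups Tukey's adjusted p equals the pooled-variance t-test p,
another identity the tests check. Cultivar means of ratio traits (the
WUEs) are means of per-leaf ratios, never ratios of cultivar means.

## 3. PLS1 core

Orthogonal-scores NIPALS for a single response, predictors mean-centred and
by default *not* unit-variance scaled — reflectance bands share units, and
scaling would inflate noisy low-variance bands; `scale=True` is available.
For univariate y the weight iteration converges in one pass and
response-side deflation is a no-op, so the algorithm is equivalent to
SIMPLS in fitted values (and to OLS at full rank, an oracle the tests hold
to 1e-8). Coefficient vectors are precomputed for every truncation 1..A via
the rotation R = W(PᵀW)⁻¹ (PᵀW is unit upper-triangular, so the solve is
stable), which lets cross-validation evaluate all component counts from n
fits rather than n·A.

Degenerate inputs: a zero-variance response returns a flagged model with
zero coefficients rather than raising; if the predictor residual runs out
of rank early the model truncates and deeper truncation requests fall back
to the deepest available.

VIP uses Wold's formula with SSYₐ = q²ₐ·tₐᵀtₐ (response variance captured
per component, computed from the stored score sum of squares and response
loading); mean(VIP²) = 1 identically, which doubles as a self-test on every
fitted model.

## 4. Component selection, splits, metrics, uncertainty

**Splits.** Random: n_cal = floor(0.8·n), the unique rule consistent with
all published random-split rows (173→138/35, 172→137/35, 163→130/33,
160→128/32). Cultivar-balanced: each cultivar contributes
ceil(0.2·n_k) leaves to validation (12 groups of 14–15 at n = 173 give
n_val = 36), guaranteeing every cultivar appears in both halves.

**LOO-PRESS.** PRESS(a) = Σᵢ(yᵢ − ŷ₋ᵢ,ₐ)² for a = 0..A_max, with a = 0 the
leave-one-out mean. Standard LOO performs n_cal fits and that is what the
package does. The search cap is A_max = min(15, n_cal − 2). Selection is
the smallest a attaining the minimum, with one numerical guard: PRESS
values within 1e-8·PRESS(0) of the minimum (the double-precision resolution
of the baseline PRESS) are treated as tied. Without this guard, noiseless
synthetic data drives PRESS down a geometric staircase of numerically
negligible improvements created by the exponential forward model (section
6 below) and
the argmin lands on meaningless extra components. A selected count of 0 is
reported as status `"no latent component"` — a scientific outcome
(the spectrum does not encode the trait), never an exception.

**Metrics.** Validation R² = 1 − SSres/SStot computed on the validation
set, which admits negative values when predictions are worse than the
validation mean ([1,2,3] vs [3,1,2] gives exactly −2); RMSE in trait
units; %RMSE = 100·RMSE/(max − min of the observed validation values). The
range denominator is a convention — mean-normalisation is equally common —
and is stated here because the two can differ by a factor of a few.

**Jackknife.** "Jackknife" here is repeated-subsample refitting: B (default
500; 200 in the pipeline) refits each on a random 80% of the calibration
leaves, giving per-band coefficient envelopes and per-validation-leaf 95%
confidence intervals as 2.5/97.5 percentiles of the B predictions. The
classical delete-one jackknife is available as `mode="delete-one"`.
Prediction intervals widen the CI by ±1.96·σ_resid, where σ_resid is the
LOO residual SD at the selected component count — so the PI carries both
sampling and residual noise. One empirical caveat the tests respect: CI
width shrinks with calibration size while subsample variability dominates,
but plateaus once the spread is dominated by per-refit noise-direction
fitting at a fixed component count; the width-vs-n monotonicity holds for
a doubling in the noise-dominated regime, not indefinitely.

## 5. Spectral regions

VIS 380–780, red edge 680–750 (deliberately overlapping VIS), NIR 780–1400,
SWIR1 1550–1750, SWIR2 2000–2300 nm. Region lookup returns a *set* so the
red edge is counted separately in VIP summaries rather than being swallowed
by VIS; gaps (e.g. 1900 nm) return the empty set. Spectra are trimmed and
linearly resampled to 400–2400 nm at 1 nm (2001 bands) before modelling —
whether to resample at all is a convention of this package, stated rather
than inherited.

## 6. Synthetic vineyard generator

The generator emulates the sampling design of a single-vineyard cultivar
panel: 12 cultivars in 7 varieties (two clones for most varieties), 3 rows
× 5 vines = 15 leaves per cultivar, 180 leaves total. Colour and origin
class are assigned at the variety level; the warm/cool origin assignment is
an arbitrary fixed label (the emulated dataset's public record does not
determine it).

**Traits.** Each trait value is mean + origin + colour + cultivar + row +
leaf effects, every effect drawn once per grouping unit from a zero-mean
normal with variance = (configured proportion) × total_sd². Effects are
normal because only variance proportions are specified; any shortfall of
the proportions from 1 is the leaf-level residual. Default means, SDs and
proportions ship as `data/default_vineyard.yaml`, seeded from the published
12-cultivar descriptive statistics; for traits whose published summary is
median-based, the mean is taken as the median and the SD as CV·median/100
(the published dispersion column is numerically consistent with that
identity). Missing cells are inserted per trait cell, completely at random,
at 3% — matching the per-trait n_obs spread of the emulated dataset.
Traits are drawn independently of each other; cross-trait correlations
(e.g. WUE with its components) are *not* emulated.

**Spectra.** reflectance(λ) = baseline(λ) · exp(−Σ links strength · z ·
gauss(λ; center, width)) + N(0, noise_sd), clipped to [0, 1], on the
2001-band grid. The baseline is a packaged 2001-point template generated by
the analytic recipe in `simulate.analytic_baseline` (low VIS with a green
bump, red-edge rise to a ~0.45 NIR plateau, 1450/1940 nm water dips, SWIR
roll-off); the packaged CSV and the recipe are asserted equal in the tests.
Default links place each trait at a physiologically sensible feature
(red edge for photosynthesis-linked traits, water bands for water
relations, SWIR dry-matter bands for structural traits); δ¹³C is linked at
1/10 strength to emulate a trait the spectrum barely encodes, and its
models duly fail or barely pass downstream. Link strengths are small
(0.03–0.1 absorbance per z-score) so the forward model operates near the
linear regime; large strengths make the exponential visibly non-linear and
PLSR then genuinely needs extra components. A leaf whose trait cell was
masked missing contributes no absorption for that link (z = 0).

**What passing tests do and do not show.** The generator provides known
ground truth for machinery validation: variance proportions are recovered
by REML, linked traits are retrieved by PLSR, unlinked regions carry low
VIP. It is *not* a radiative-transfer model: band noise is i.i.d. (real
sensor noise is structured), absorption features are Gaussian and
independent per trait, and the trait–spectrum coupling is far cleaner than
in field data — validation R² near 1 on defaults says nothing about
achievable field R². Conclusions about real leaves require real spectra.

## 7. Pipeline

Stage order: derive → transform + Shapiro screen → IQR outlier masking →
split → LOO-PRESS selection → final calibration fit → validation metrics →
jackknife. Outliers are masked before splitting. Both splitting strategies
always run; failed models appear in the report with their status, never
silently dropped. All outputs are CSV plus a JSON manifest (seeds, library
versions, per-trait outlier tallies, row counts) and a plain-text log;
nothing in the bundle carries a timestamp, so a fixed configuration
reproduces the bundle byte for byte — asserted in the tests by comparing
two runs file by file.

Problem sizes used by the test suite and acceptance script (compact
configurations of the same generator): 4-trait vineyards for pipeline
checks, 100 replicate vineyards for REML recovery, 1000 null simulations
for ANOVA calibration, 20 random problems per algebraic oracle. These sizes
give Monte-Carlo error comfortably inside the asserted tolerances.

## 8. Known limitations

- Origin/colour enter as two-level factors; their REML variance shares are
  high-variance estimates by construction.
- The repeated-subsample jackknife quantifies calibration-sampling
  uncertainty at a fixed component count; it does not propagate
  component-selection uncertainty.
- The generator draws traits independently and encodes each through fixed
  Gaussian features; covarying traits sharing absorption features (the
  realistic case) make attribution harder than these tests exercise.
- Instrument-native formats (.sig), splice correction and white-reference
  processing are out of scope; CSV reflectance fractions are the interface.
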