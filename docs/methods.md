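# Methods

## Data model and normalization

Raw measurements live in a tidy long-format table keyed by
(attribute, treatment, temperature °C, time days, replicate). Kinetic
analysis operates on per-condition series normalized to the **day-0
replicate mean**: mean_norm(t) = mean_raw(t) / mean_raw(0), and likewise for
the dispersion. A single baseline per condition (rather than per-replicate
baselines) matches how such studies report one initial value per attribute;
it also makes normalization idempotent. A zero or missing day-0 mean is an
error, not a silent fallback.

Colour is handled separately: CIELAB records are averaged to cell means per
(treatment, temperature, time) and summarized as ΔE, the Euclidean distance
from the same condition's day-0 cell mean. Instrument-side per-pixel
averaging is not reproducible from tabulated data, so ΔE values computed
from cell means are comparable in shape but not guaranteed to match
instrument-reported magnitudes.

### Modellability screen

An attribute enters kinetic fitting only if its normalized series shows a
usable monotone trend. The screen regresses mean_norm on time and excludes
the series only when *both* indicators fail: two-sided slope p > α (default
0.05) *and* preliminary R² < 0.30. The conjunction is deliberate — a
significant slope with modest R², or a strong R² with few points, each keep
the attribute in play. A perfectly flat series is handled without numerical
warnings (slope 0, R² 0, p = 1, excluded). Both indicators are invariant
under rescaling of the time axis, so the verdict does not depend on whether
time is recorded in days or hours.

## Kinetic fitting

Both pseudo-orders are linear on a working scale and are fitted by OLS:
the normalized values themselves (zero order) or their natural log (first
order). Decisions worth making explicit:

- **k is a magnitude plus a direction flag** (+1 rising, −1 decaying).
  The kinetic law is conventionally written with −kt even though some
  attributes (pH) increase during storage; separating sign from size keeps
  percent-reduction arithmetic and shelf-life inversion unambiguous.
- **R² on the working scale, RMSE on the original scale.** R² describes the
  regression actually performed; RMSE is computed from back-transformed
  predictions so zero- and first-order fits are compared in the same units
  (normalized quality, where typical values are 0.01–0.06).
- **Uncertainty** comes in two forms, both reported: the regression standard
  error of the slope, and the across-replicate SD of k obtained by fitting
  each replicate separately (each normalized by the shared condition
  baseline). Published tables of such studies report k ± SD of triplicates;
  the per-replicate route is the mechanism that reproduces that convention.
- **Log-linear, not nonlinear, first-order fitting.** The field's standard
  workflow fits ln A by linear regression; a nonlinear refit would weight
  errors differently and is out of scope.

### Residual-pattern diagnostic

"No systematic pattern in residuals" is made concrete as a Wald–Wolfowitz
runs test on residual signs: few runs mean residuals cluster on one side of
the fitted curve (the signature of a misspecified order). The null
distribution of the run count is exact (combinatorial) for n ≤ 20 — every
design this package targets — with a continuity-corrected normal
approximation beyond. The p-value is the lower tail P(R ≤ r_obs); p < 0.05
flags the fit. Residuals within 1e-12 of zero are dropped first; an all-zero
residual vector (perfect fit) skips the test without flagging; fewer than 4
informative residuals raise an error rather than returning an unstable
p-value.

### Order selection

First order is retained only when it *dominates*: ΔR² > tol_r2 (default
0.01), RMSE no worse, and residuals no more patterned than the zero-order
fit. Ties and conflicts fall back to zero order. The tie-break is principled:
when k·t_max is small, exp(−kt) ≈ 1 − kt and the two models are empirically
indistinguishable, so the simpler one is reported. A consequence, verified
by simulation: with the reference design's noise (SD 0.02) the selector
needs substantial curvature (k·t_max ≈ 1, e.g. the antioxidant-like rate
0.064 day⁻¹ over 15 days) to pick first order ≥95% of the time; near the
linearization boundary (k·t_max ≈ 0.6) the tie-break fires roughly half the
time — by design, since either model then predicts equally well.

## Arrhenius modelling

OLS of ln k on 1/T gives Ea = −slope·R (reported in kJ mol⁻¹) and
ln A0 = intercept; k_ref is *derived* from the fitted curve at T_ref, so
changing the reference temperature changes k_ref but never Ea or any
prediction. T_ref defaults to 277.45 K, the value conventionally printed in
refrigerated-storage studies (kept verbatim even though 4 °C is 277.15 K;
it is a configurable parameter, and the 0.3 K difference is immaterial at
these Ea values). °C→K conversion adds 273.15. Unweighted OLS is the
default; inverse-variance weighting by se(ln k) = k_se/k is an option.
Two distinct temperatures produce an exact fit with a warning and undefined
R²; fewer raise.

Activation energies of two arms are compared by
z = (Ea_A − Ea_B)/√(se_A² + se_B²), against a normal reference when only
the fitted SEs are available, or a Welch–Satterthwaite t when replicate-level
sample sizes are supplied. With triplicate per-replicate fits the t version
holds its nominal size (verified by a 1000-draw null simulation in the test
suite).

## Group inference

- **Percent reduction**: 100·(k_control − k_prototype)/k_control, reported
  to the nearest integer by convention.
- **Balanced three-way ANOVA** (treatment × time × temperature, all
  interactions, F against within-cell residual MS) is computed by the
  classical cell-means decomposition — R(S) terms with inclusion–exclusion —
  which is exact for balanced data, where Type I/II/III SS coincide.
  Unbalanced input raises; the engine does not silently switch SS types.
  The decomposition is verified against statsmodels and against direct
  mean-contrast arithmetic in the tests, and its null size is calibrated by
  simulation.
- **Duncan's multiple range test**: for a stretch of p ordered means the
  critical range is q(1−α_p; p, df)·√(MSE/r) with protection level
  α_p = 1−(1−α)^(p−1). Stretches whose range is below their critical value
  are homogeneous, sub-stretches are shielded, and the compact letters mark
  the maximal homogeneous stretches. Equal group sizes only (the triplicate
  design); with two groups the procedure reduces exactly to the two-sample
  t-test on the same error term. The error term is the caller's choice;
  the intended use is the within-cell residual MS from the ANOVA.
- **Rate-constant comparisons** use Welch t with across-replicate SDs when
  available (df from Satterthwaite), else regression SEs; stars follow the
  0.05/0.01/0.001 convention.
- Shapiro–Wilk and Levene diagnostics are exposed as pass-through
  information only; the pipeline never auto-switches to nonparametric
  alternatives.

## Shelf-life prediction

Acceptability limits are mandatory user input — where a quality index stops
being acceptable is a product decision the kinetics cannot supply, so no
default is shipped and all shelf-life numbers are demonstrative. Constant
temperature inverts the kinetic law in closed form; piecewise-constant
profiles accumulate k_i·Δt_i on the working scale (original scale for zero
order, log space for first order) and interpolate the exact crossing time —
both laws are linear in time within a segment, so no ODE integration is
involved. Unreachable limits return an infinite sentinel rather than the
profile's end time.

## Synthetic studies

The generator emulates the reference design: 2 treatments × 3 temperatures
(1/4/8 °C) × 6 sampling days (0, 2, 5, 7, 9, 15) × 3 replicates; four
attributes with baselines pH 4.12, TA 3.52 mL, TPC 1.9 mg GAE eq g⁻¹dw,
AOC 16.85 mg Trolox g⁻¹dw; zero-order kinetics for pH (rising), TA and TPC
(decaying), first-order for AOC (decaying); rates linked across temperature
by the Arrhenius relation from per-treatment (k_ref, Ea). The default
parameter set uses the published 4 °C rate constants as k_ref (the reference
temperature is ~4 °C, and the tabulated per-temperature rates carry more
digits than the published k_ref column) and the published per-treatment Ea
values.

Noise is i.i.d. additive Gaussian on the normalized scale, SD 0.02 by
default — the simplest structure consistent with reported near-constant SDs
and RMSE magnitudes of 0.01–0.06; a multiplicative option exists. What this
does **not** emulate: fruit-to-fruit vs assay variance components (collapsed
into one term), non-monotone colour dynamics, microbial counts, or any
serial correlation within a replicate — so passing tests demonstrate
correctness of the estimators under the stated model, not robustness to
real-data pathologies. First-order trajectories pushed non-positive by noise
are clipped to a 1e-6 floor with a warning.

Reproducibility: one global seed is combined with a CRC32 hash of each
condition key to seed an independent substream per (attribute, treatment,
temperature), so equal seeds give bitwise-equal tables and adding a
condition never perturbs the draws of existing ones.

### Monte-Carlo validation

`recovery_experiment` repeatedly generates a study, runs
normalize → kinetic fit (true order) → Arrhenius, and reports bias, RMSE,
empirical SE and 95% t-interval coverage for k at each temperature and for
Ea (interval df = points − 2). Under the reference design with k_ref
0.02 day⁻¹, Ea 46 kJ mol⁻¹ and noise SD 0.02, 500 simulations show bias
within Monte-Carlo error and Ea coverage ≈ 0.95.
`order_selection_experiment` tallies the chosen orders and tie-break rate on
simulated single conditions. Problem sizes in the test suite (400–1000
simulations depending on the check) were chosen to give binomial Monte-Carlo
error comfortably inside the asserted bands.

## Known limitations

- Published parameter tables for the reference study are not exactly
  recomputable here: the raw measurements are not deposited, and refitting
  the Arrhenius model to the published *rounded* per-temperature rates gives
  Ea values several kJ mol⁻¹ away from the published ones (which were
  presumably fitted per replicate on unrounded rates). The bundled
  reference fixture is therefore a validation surface for arithmetic built
  on top of it (percent reductions, comparison statistics), not a target
  for re-estimation.
- The published first-order AOC rates (0.064–0.083 day⁻¹) imply 62–71%
  losses over 15 days, while the narrative reports 10–15% drops; the two
  cannot both hold. Downstream arithmetic here uses only the internally
  consistent tabulated rates.
- Balanced designs only, fixed effects only; no mixed models,
  repeated-measures corrections, Weibull or second-order kinetics, or
  microbial-growth-based shelf life.
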