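# Methods

## Scope and data model

`egikit` analyzes in vitro carbohydrate-digestion experiments in which a
food passes simulated oral, gastric and intestinal phases and starch
hydrolysis is assayed at 0, 15, 30, 45, 60, 90 and 120 min of the
intestinal phase (t = 0 at simulated-intestinal-fluid addition). The
package computes, per food: the hydrolysis percentages S60/H90/S120, the
AUC-based hydrolysis index HI, two estimated-glycemic-index predictors,
and validation statistics against human GI values. It does not model the
physics of digestion (pressure, particle breakdown, enzyme-activity
decay, pH trajectories); those are measured quantities upstream of this
analysis.

## Hydrolysis quantification

Raw reducing-sugar measurements are converted with the anhydroglucose
factor 0.9 = 162/180: `hydrolysis % = Gt × 0.9 / TS × 100`. The glucose
standard curve (0–1 mg/mL, absorbance at 520 nm) is fitted by OLS and
inverted with an optional dilution factor; negative concentrations are
clipped to zero with a warning.

Assay noise can push percentages slightly outside [0, 100]. Values within
±2 percentage points of the bounds are clipped with a logged warning;
anything further is rejected as a probable unit error. The ±2 band is a
package choice calibrated to typical reducing-sugar assay scatter.

## Curve summaries

- Interpolation is linear and extrapolation is never performed — with a
  7-point grid there is no defensible basis for it.
- AUC uses the composite trapezoid rule on the sampled grid, with
  interpolated endpoints for off-grid windows. The default metric window
  is [0, 120] min.
- HI = 100 × AUC(curve)/AUC(reference). No reference food is prescribed
  by the eGI formulas used here, and the kinetic formula's magnitudes
  (eGI − A − macronutrient terms roughly 40–50 for cereals) are only
  consistent with HI on a 0–100 scale, not with raw %·min areas (10³–10⁴).
  The default reference is therefore the ideal instantaneous-digestion
  curve (constant 100 %), which bounds HI to [0, 100]; an explicit
  reference curve (e.g. white bread digested under the same protocol)
  can be supplied for a conventional Goñi-style index. This normalization
  is a documented package choice, not an experimentally fixed convention.
- "Hydrolysis rates at 60 and 120 min" are read as cumulative percent
  hydrolyzed at those times, not instantaneous derivatives: derivative
  ratios would be dimensionally inconsistent with a 0–100 HI and
  numerically unstable on 7-point grids.

## eGI predictors

Single-point: `eGI = 39.21 + 0.803 × H90`. Kinetic:
`eGI = A + (S60/S120) × HI − 0.26·Protein + 0.54·Fat − 0.43·Fiber`, with
A = 30 when carbohydrate strictly exceeds 55 g/100 g and 15 otherwise
(the boundary value 55.0 maps to 15, reading "exceeds" literally; the
threshold is configurable). The kinetic term is parsed as
(S60/S120) × HI. All coefficients are fixed empirical constants exposed
through `EgiCoefficients`; the package does not refit them. Predicted
eGI is never clamped — negative or >110 values are flagged, not altered.

Replicate curves are averaged pointwise before metric extraction
(replicates on differing grids are interpolated onto the union of times
within their overlap). An all-zero curve has no defined S60/S120 ratio;
such foods are reported as skipped rather than silently assigned A.

## Validation

Deviation % = (GI_human − eGI)/GI_human × 100, reported at 1 decimal in
tabular output and full precision internally. The regression convention
is x = human GI, y = eGI; this orientation reproduces the published
reference lines from the packaged 14-food table (verified against a
normal-equations oracle before freezing). Slope/intercept/r are printed
at 4/2/2 decimals. No confidence intervals are computed. Regression
fields require ≥ 3 paired foods and non-constant GI.

## First-order kinetic model and fitting

Curves are summarized by `C(t) = c0 + (c_inf − c0)(1 − e^(−kt))` with
0 ≤ c0 ≤ c_inf ≤ 100 and k ∈ [0, 1] min⁻¹. Fitting is bounded nonlinear
least squares (trust-region reflective) with a deterministic multi-start:
c0 starts at the first sampled value, c_inf at the last, k on
{0.005, 0.02, 0.05} min⁻¹; the best-RSS converged start wins. Tolerances
are set to 1e−15 so noiseless synthetic curves recover their generating
parameters to ≤ 1e−6 relative error. A flat curve leaves k unidentifiable;
it is reported as k = 0 with the `k_indeterminate` flag rather than an
arbitrary fitted value. Fits require ≥ 4 points spanning ≥ 60 min.

## Synthetic data generator

The generator emulates sigmoid-free first-order hydrolysis curves with
additive Gaussian assay noise truncated to [0, 100] (default sd 2 %, a
stand-in consistent with triplicate mean ± SD reporting, not a published
value). All randomness flows from an explicit seed; outputs are pure
functions of (config, seed).

Scenario presets reproduce published cereal endpoints for
{rice, corn, millet} × {small, large grain} × {dynamic, static}. A preset
pins c0 to the published 0-min hydrolysis where one exists (small-grain
rice: 10.2 % dynamic, 8.3 % static) and to a 5 % default otherwise
(flagged `default_c0`). The 120-min endpoint leaves (c_inf, k)
underdetermined, so the package closes the system by fixing the plateau
fraction reached at 120 min to 0.98, giving k = −ln(0.02)/120 ≈ 0.0326
min⁻¹ and c_inf = c0 + (C120 − c0)/0.98. This keeps c_inf ≤ 100 for every
published endpoint (worst case ≈ 97.6) and passes through each printed
120-min value exactly.

Synthetic food panels draw composition uniformly over ranges spanning a
mixed real-food panel (carbohydrate 3–95, protein 0–36, fat 0–22, fiber
0–10 g/100 g) and kinetics (c0 ∈ [2, 12], c_inf ∈ [20, 98], log-uniform
k ∈ [0.005, 0.05]) so HI spans roughly 10–90. The "true" eGI is the
kinetic formula evaluated on the noiseless curve; human GI is truth plus
N(0, 5) by default (floored at 1 to keep GI positive), so validation
should recover slope ≈ 1, intercept ≈ 0.

What passing on synthetic panels shows — and what it does not: the
generator's curves are exactly first-order and its human GI is exactly
truth plus Gaussian noise, so recovery tests certify the arithmetic and
plumbing of the pipeline, not the empirical adequacy of either eGI
formula for real foods. Real digestion curves can be sigmoidal or
biphasic, replicate noise is not Gaussian or homoscedastic, and human GI
error is not centered on any in vitro prediction.

## Numerical and degenerate-input policy

- Strictly increasing times, ≥ 2 points per curve; duplicate (key, time)
  rows are load errors.
- Zero-width AUC windows, extrapolation requests, non-positive reference
  AUC, s120 = 0, constant-x regressions and human GI ≤ 0 all raise typed
  errors instead of returning sentinel values.
- Report rounding: eGI and deviations at 1 decimal; regression summary at
  4/2/2 decimals; raw precision retained in JSON output.

## Known limitations

- The packaged reference table transcribes published per-food eGI values;
  the hydrolysis metrics behind them were not published, so those columns
  validate the regression/deviation machinery, not the curve-to-eGI path
  (which is certified by the synthetic pipeline-identity tests instead).
- The default HI normalization is a package convention (see above);
  results with an explicit reference food are not comparable to results
  under the default without renormalization.
- The kinetic formula's fixed coefficients inherit the food panel and
  digestion protocol they were calibrated on; the package applies them
  verbatim.

## Problem sizes

Test and acceptance runs use panels of 6–200 synthetic foods, 7-point
curves, and Monte-Carlo batches of 200–500 replicates — sizes chosen to
exercise every code path and give stable Monte-Carlo estimates with
sub-minute runtimes.
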