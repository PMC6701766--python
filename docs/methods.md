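# Methods

`pedovox` implements catchment-scale 3D digital soil mapping of soil organic
carbon (SOC) with spatially modelled depth functions, alongside the
conventional multi-layer ("2.5D") approach it is compared against, and a
synthetic catchment generator that makes the whole chain testable end to end.

## The model

Soil profiles sampled at depth increments (0–5, 5–10, 10–20, 20–30,
30–50 cm) are summarised per plot by one of four depth functions of depth
*x* in cm:

- cubic polynomial `f(x) = c0 + c1 x + c2 x² + c3 x³`
- quadratic polynomial `f(x) = c0 + c1 x + c2 x²`
- logarithmic `f(x) = c1 ln(c2 x)` (undefined at x = 0)
- exponential `f(x) = exp(c1 + c2 x)`

All families are fitted by linear least squares: polynomials on the
polynomial design, the exponential on `ln(value) ~ depth` (c1 = intercept,
c2 = slope), the logarithmic on `value ~ ln(depth)` (slope = c1, intercept
a ⇒ c2 = e^(a/c1)). The log-linear fit of the exponential family carries the
usual retransformation bias; this is accepted and documented rather than
corrected, because the fit must stay a *linear* least-squares problem. Fit
metrics (per-profile and pooled R², RMSE) are always computed on the original
property scale; pooled R² uses the explained-variance form 1 − SSE/SST so a
grand-mean predictor scores exactly 0.

Fitting uses the increment **mid-depths** (2.5, 7.5, 15, 25, 40 cm) as the
depth coordinate, consistent with how the 2.5D layers are labelled.
Integral-matched fitting (matching increment averages instead of mid-depth
points) would be a defensible alternative; mid-depth fitting was chosen so
the 2.5D and 3D pipelines share one depth convention. Increments are
unweighted despite unequal thickness. Per-profile fits are not
cross-validated — with five points per profile there is nothing to hold out.

The fitted coefficients are then treated as soil properties: each is
predicted over the grid from terrain covariates by a regression model, and
the depth functions are solved at every cell over a regular depth grid
(default 0–50 cm in 5 cm steps, i.e. 11 levels) to produce a voxel model.
Depth levels denote the **lower corner** of a voxel; the slab covered by a
level *d* is (d − dz, d], so a 0 cm level carries no volume. Validation and
3D-vs-2.5D comparisons, by contrast, are made at increment mid-depths. Both
conventions are explicit parameters. For the logarithmic family the depth
grid must start at the first positive level.

Negative predictions are possible for polynomial families; SOC voxels are
clamped at a floor of 0 and the clamp count recorded. Clamping is
`max(value, floor)`: it never lowers a value and leaves everything at or
above the floor untouched. Bulk density (BD) is not clamped by default.

## Terrain covariates

The base catalogue derives one well-defined estimator per attribute: slope,
eastness/northness (sine and cosine of the aspect of steepest descent —
aspect itself is never emitted because of its circularity), plan, profile
and tangential curvature from an Evans-style quadratic surface fit over the
3×3 window (edge cells use replicated padding); catchment area by top-down
multiple-flow-direction accumulation with slope-weight exponent 1.1; TWI =
ln(specific catchment area / tan slope) with slope floored at 1e−6 rad on
flat cells; the Moore–Burch LS factor; and vertical distance to the channel
network (channels = cells above a contributing-area threshold, default
1 ha), following the D8 steepest-descent path and reporting the elevation
drop, with pit elevation as local base level where the path ends off-channel.

Field practice often derives many variants of each attribute with different
published estimators; re-implementing that catalogue adds no testable
behaviour, so a stack can instead be padded by duplicating attributes under
distinct provenance tags when a count-compatible 58-layer catalogue (hence
58 × 5 = 290 after smoothing) is needed.

Every attribute is expanded across scales with circular mean filters (cells
whose centre distance ≤ radius; reference radii 1, 2, 4, 6, 8 pixels ≈ up to
the ~90 m catena scale at 5 m cells). Edge cells use the truncated
neighbourhood — no padding — which keeps the filter an exact mean of
available data. The multi-scale stack contains smoothed layers only (the
290 = 58 × 5 arithmetic implies the unsmoothed originals are not kept; a
`keep_original` flag restores them if wanted). The stack is then centred and
scaled per layer; constant layers are dropped with a warning, and the stored
means/sds can be re-applied to new data.

## Learners and tuning

Three interchangeable engines sit behind one contract:

- **rf** — random forest, 500 trees (fixed), tuned over
  mtry ∈ {⌊p/10⌋, ⌊√p⌋, ⌊p/3⌋} clipped to [1, p];
- **svm_rbf** — ε-insensitive support-vector regression with RBF kernel
  `exp(−σ‖x−y‖²)`, ε = 0.1, cost ∈ {0.25, 0.5, 1, 2, 4}, σ candidates from
  the {0.1, 0.5, 0.9} quantiles of the inverse squared pairwise distances on
  a deterministic subsample (≤ 100 rows);
- **mars_like** — an adaptive piecewise-linear basis expansion written for
  this package: a forward pass greedily adds reflected hinge pairs
  max(±(x−t), 0) (knots at response-independent data quantiles, optional
  interactions up to a degree limit), and a backward pass prunes by
  GCV = MSE / (1 − C(M)/n)² with C(M) = M + 3(M − 1). Tuned over degree and
  max_terms. The contract is the behaviour (adaptive hinge regression with
  degree and term tuning), not binary compatibility with any particular
  spline package.

All learners for one dataset share a single random balanced fold partition
(10-fold by default; SOC n = 67 folds into seven 7s and three 6s). For each
grid point, out-of-fold predictions are pooled over the folds and the mean
RMSE computed; the lowest-RMSE point is refit on all data. Grid points are
enumerated simplest-first and selection uses a strict minimum, so ties break
toward the simpler model. Explicit grids replace "package defaults" because
reproducibility requires the grid to be stated.

Feature reduction (PCA etc.) is deliberately absent: the engines tolerate
collinear, n < p covariate sets, and variable-importance interpretation is
out of scope.

## Evaluation statistics

R² is the squared Pearson correlation of observed vs predicted (the form
that pairs naturally with concordance statistics; 1 − SSE/SST is available
behind a flag and is used for depth-function fit quality). RMSE is reported
in property units; nRMSE divides by the observed range of the target, making
coefficients with different units comparable. Lin's concordance correlation

    ρc = 2 s_xy / (s_x² + s_y² + (x̄ − ȳ)²)

uses sample (n − 1) moments and satisfies |ρc| ≤ |r|. The 3D-vs-2.5D
comparison evaluates the 3D model at the increment mid-depths over **all**
shared grid cells (a plots-only restriction is available via the mask
argument) and tabulates R², ρc and RMSE per depth plus their mean.

## Stocks

Per voxel, `stock = SOC/100 × BD × cell_size² × dz` in grams (units:
% → fraction, g cm⁻³, cm², cm); the reference voxel (500 × 500 × 5 cm) holds
1.25 m³ of soil. Coarse-fragment correction is omitted — the emulated site
has a negligible (< 5 vol-%) coarse fraction. SOC and BD are modelled
separately and multiplied afterwards ("model-then-calculate"); this suits
datasets where the BD plots are a subset of the SOC plots. Aggregation sums
voxel stocks over an explicit depth interval and optional spatial mask and
converts to Mg ha⁻¹; it also accepts pre-aggregated per-increment densities
and simply sums them. Aggregation bounds are always explicit parameters
because "whole interval" is ambiguous whenever the voxel model extends
deeper than the deepest sample.

## Synthetic catchment

The generator supplies the study conditions: a 110 × 110 cell DEM at 5 m
(~30 ha) with elevation rescaled into 105–275 m, built from a sinuous-valley
template with convex side slopes plus a Gaussian-filtered random field
(roughness 0.35, smoothing length 6 px) — a recipe chosen to give realistic
flow routing, with all parameters exposed; 67 plot cells drawn without
replacement, 55 of them flagged for BD; and terrain-linked "true" coefficient
fields: each coefficient grid is intercept + weighted standardized covariates
+ smooth unit-variance noise, clipped to a range.

The reference SOC truth is exponential — surface SOC rises with wetness (TWI)
and falls with slope, the decay rate steepens on steep cells — with clip
ranges (c1 ∈ [0.80, 1.55], c2 ∈ [−0.045, −0.025]) chosen so every mid-depth
evaluation stays inside the SOC bounds [0.35, 5.06] %; the BD truth is
logarithmic (c1 ∈ [0.24, 0.28], c2 ∈ [10, 15]) keeping BD inside
[0.75, 1.84] g cm⁻³ and increasing with depth. Those bound choices make the
noiseless generator exactly in-family, which is what the end-to-end recovery
tests require. Profile values are the function evaluations at the increment
mid-depths plus additive Gaussian noise (defaults: 0.15 % SOC,
0.05 g cm⁻³ BD — low relative to the property ranges, emulating bulked-core
composite sampling) and are clipped into the property bounds, the lower
bound doubling as the positivity floor.

What the generator does **not** emulate: spatial autocorrelation of the
noise, preferential (non-random) plot placement, measurement error structure
that varies with depth, non-monotone profiles, and any soil-forming factor
other than terrain. Passing recovery tests therefore demonstrates that the
machinery recovers a terrain-driven signal under realistic noise — not that
any particular real catchment satisfies these assumptions.

## Numerical choices and degenerate inputs

- Closed-form integrals per family, with the exponential c2 → 0 limit
  handled analytically (|c2| < 1e−12 switches to the constant limit).
- Log-family fits reject |c1| < 1e−12 (c2 would be undefined); exp fits
  reject non-positive values; underdetermined fits (fewer points than
  coefficients) are rejected.
- Profiles whose fit fails are excluded with a warning; if more than 20 % of
  a dataset's profiles fail, the 3D run aborts.
- Flat DEM cells floor tan(slope) at 1e−6 for TWI/LS; aspect-derived
  eastness/northness are 0 on flat cells.
- Flow accumulation processes cells in strictly decreasing elevation order
  with a stable sort, so results are deterministic and mass-conserving: the
  accumulated area over cells without a lower neighbour equals the total
  grid area.
- All randomness flows through `numpy.random.default_rng` seeds carried in
  the configuration; reruns are byte-identical.

## Problem sizes

The reference configuration (110 × 110 grid, 50 covariate layers, 67/55
plots, 10-fold CV, rf with 500 trees) runs the full 2.5D + two-family 3D
comparison in a few minutes on one CPU; unit tests use a 40 × 40 catchment
and smaller learner grids. These sizes were chosen as the package's
desk-scale defaults and are stated here so results can be reproduced
exactly.

## Known limitations

- The exponential fit's retransformation bias slightly underestimates the
  mean on noisy data (documented above).
- The MARS-style learner's exhaustive forward search is O(terms × p × knots)
  per step and is meant for the n ≪ 1000 regime this package targets.
- GeoTIFF interchange stores geometry as JSON metadata rather than geo tags,
  so files are self-describing within the package but not georeferenced for
  GIS use.
- No uncertainty propagation into stock estimates; no equal-area spline
  depth functions; no vertical interpolation between 2.5D layers.
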