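# Methods

## The necessity model

Given paired observations `(x_i, y_i)`, the scope is the rectangle
spanned by the observed extrema, `(x_max − x_min) × (y_max − y_min)`.
Scope bounds are always the *sample* extrema — even when the data are
known to live on [0, 1] — because the effect size is defined relative to
the observed data cloud, not a theoretical support. Datasets with
constant x or constant y have zero scope area and raise an
`UndefinedScopeError` rather than returning a value.

**Peers (ceiling points).** Observations are first collapsed to the
maximum y per distinct x (the step ceiling only depends on the per-x
maximum, and this makes "all points at lower x" unambiguous when x is
tied). A collapsed point is a peer when its y strictly exceeds the y of
every point at strictly smaller x. Strictness resolves ties in the
maximum outcome: if several x positions attain `y_max`, only the
leftmost is a peer. The peer sequence is strictly increasing in both
coordinates, which is asserted on every call.

**CE-FDH.** The step ceiling through the peers leaves an empty zone of
area `Σ_i (x_{i+1} − x_i)(y_max − y_i)` with the last strip ending at
`x_max`; the effect is that area divided by the scope area. It is
defined for every valid dataset and lies in [0, 1] by construction.

**CR-FDH.** Ordinary least squares through the peers gives the ceiling
line; the empty zone is `∫ (y_max − clip(line, y_min, y_max)) dx` over
`[x_min, x_max]`. Clipping keeps the effect inside [0, 1]: where the
line exceeds `y_max` the strip contributes nothing, where it falls below
`y_min` the strip contributes full height. The integral is evaluated in
closed form — the clipped height is piecewise linear, so the area is a
sum of exact trapezoids split at the clip crossings; no numeric
quadrature is involved. With fewer than two peers the line is
unidentified and the effect is reported as *missing* (`None`/NaN), never
as zero and never as an error: downstream regressions exclude such
replications with a logged count.

**Corners.** The default (upper-left) corner encodes "high Y requires
high X". The upper-right corner — "high Y requires *low* X" — is
computed by negating x, applying the same estimator, and mapping the
peers and ceiling line back to original units (a line `y = a + b·x'` on
reflected data becomes `y = a − b·x`); effect values are exactly
reflection-invariant. Bottleneck tables invert the ceiling line,
`x* = (y* − intercept) / slope`, and read "at least x*" for the
upper-left corner, "at most x*" for the upper-right; a zero slope has no
inverse and raises a "ceiling flat" error.

**Verification oracle.** `empty_zone_oracle` rasterizes the scope into
`R × R` cells and counts cell centers `(u, v)` with no observation at
`x ≤ u, y ≥ v`. This brute-force count is the same free-disposal-hull
notion evaluated pointwise, so it converges to the CE-FDH effect at rate
O(1/R); tests require agreement within `2/R`. It exists only to check
the analytic implementation and is never used for estimation.

## Skewness

Sample skewness is the method-of-moments ratio `g1 = m3 / m2^{3/2}`
(central moments with denominator n, no small-sample correction),
matching the estimator conventionally used in this literature. The
analytic skewness of Beta(α, β) is
`2(β − α)√(α + β + 1) / ((α + β + 2)√(αβ))`. The logit and its inverse
carry effects between the unit interval and the real line; a logit of an
exact 0 or 1 raises a `BoundaryEffectError` so the *caller* decides the
exclusion policy — nothing is silently clamped.

## The simulation study

The study asks how much necessity effect appears between *independent*
variables as a function of marginal shape alone. Its design is fixed:
sample sizes {50, 200, 800, 3200, 12800} crossed with seven beta shapes
per variable — (9,1), (9,2), (9,3), (9,9), (3,9), (2,9), (1,9),
population skewness −1.47, −0.88, −0.59, 0, +0.59, +0.88, +1.47 — giving
245 cells; X and Y are drawn mutually independently. The reference
replication count is 1000 per cell (245,000 datasets); the replication
count is a first-class parameter and the package's own headline numbers
are computed at 200 per cell (49,000 datasets, a few minutes on one
CPU), which leaves all fitted coefficients within a few hundredths of
their full-scale values.

Each replication records both effects and the observed sample
skewnesses. Seeding is counter-based: replication `(cell, rep)` uses
`default_rng([master_seed, cell_index, rep])`, so runs are bit-for-bit
reproducible, any single dataset can be redrawn in isolation, and cells
could be computed in any order or in parallel without changing results.

The per-cell empirical standard error is the sample SD (denominator
n − 1) of the effect across the cell's valid replications — the only SE
computable from the stated design; cells with fewer than two valid
CR-FDH replications get a missing CR summary.

What the generator deliberately does *not* emulate: any dependence
between X and Y (the point is the independence baseline), non-beta
marginals, measurement error, or discreteness/ties — real psychometric
data have all four. Passing tests therefore show that the estimators and
meta-models behave correctly under the independence-plus-beta model, not
that any particular real dataset is free of necessity.

## Meta-models

The **effect model** regresses `logit(effect)` on
`{1, Skew(X), Skew(Y), Skew(X)·Skew(Y)}` across records, using each
dataset's *observed* skewnesses by default (a `skew_source="design"`
switch exists, since either reading of the original analysis is
defensible; observed is the default because the per-dataset skewnesses
were the quantities recorded alongside each effect). Records with
missing effects or boundary effects (exactly 0 or 1, logit undefined)
are excluded with a logged count — in practice a handful out of tens of
thousands. The **SE model** regresses `log(SE)` on
`{1, √N, Skew(X), Skew(Y)}` across cells, using the *design* skewnesses,
which are the covariates actually fixed by each cell. R² is
`1 − SSE/SST` about the outcome mean in both families. The published
coefficient sets from the original full-scale study ship as constants so
that expectations and CIs are available without simulating.

The confidence interval is `expected ± 2·SE` — the multiplier is exactly
2, not 1.96 — and the bounds are reported untruncated even when they
leave [0, 1], with a flag (`ci_outside_unit`) rather than silent
clipping. Predicted effects live in (0, 1) via the logit link; predicted
SEs are positive via the log link.

**Meta-NCA.** The method applied to its own output: each simulated
dataset contributes its CR-FDH effect as the outcome, and observed
Skew(X) (upper-right corner, since *low* predictor skewness enables high
effects), observed Skew(Y) (upper-left) and N (upper-left) act as
predictors. The bottleneck tables invert the two skewness CR ceilings at
outcome levels {0.1, 0.3, 0.5} — the conventional medium/large/very
large thresholds. At the default study conditions both skewnesses show
large necessity effects (≈ 0.4–0.47 at 200 replications per cell) and
sample size shows none (CE effect exactly 0; the CR ceiling for N is
typically unidentified because the smallest N carries the global
maximum, and is then reported missing). The originally reported
magnitudes for this particular meta-analysis (≈ 0.35 for both
skewnesses, bottleneck thresholds ≈ ∓0.9 at level 0.3) are *not*
recovered by this construction even at the full 245,000-dataset scale,
although the same run reproduces the published effect-formula
coefficients to the third decimal; the discrepancy is documented in the
acceptance checks rather than papered over, and the qualitative
conclusions (large skewness effects, nil sample-size effect, ordering of
bottleneck requirements) are insensitive to it.

## Numerical choices and edge cases

- Peer scan, CE area and CR integration are exact float arithmetic on
  sorted arrays; no tolerances enter the estimators themselves.
- OLS fits for the meta-models go through a rank check first; collinear
  designs raise `UnfittableModelError` instead of returning pseudo-fits.
- The effect model refuses to fit on fewer than 10 usable records, the
  SE model on fewer than 5 usable cells.
- Input tables: delimiter inferred from extension (`.tsv` → tab,
  otherwise comma), columns by name or 0-based index, non-numeric rows
  dropped with a logged count, fewer than 3 usable rows is an input
  error.
- CLI exit codes: 0 success, 2 input error, 3 numeric/degenerate-data
  error. Output artifacts embed package version, seed and a config hash.

## Known limitations

- Single-predictor analyses only; no multi-X simultaneous NCA, no other
  ceiling families (CE-VRS, quantile ceilings), no permutation tests.
- The expectation models interpolate within the simulated skewness range
  (±1.47 by design, somewhat wider in observed values); extrapolating to
  |skewness| ≫ 2 leaves the calibrated region, and Table-style
  expectations at skew(Y) = 2.2 already sit near its edge.
- The CI is a plain two-SE band around a point prediction; it ignores
  coefficient uncertainty in the meta-models themselves.
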