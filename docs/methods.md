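# Methods

This note documents the statistical model, the numerical choices, and the
limits of what the package's tests demonstrate.

## Model

Each critical method attribute (CMA) `y` is modelled independently as a
quadratic polynomial in coded factor levels:

    y = b0 + Σᵢ bᵢ xᵢ + Σᵢ bᵢᵢ xᵢ² + Σᵢ<ⱼ bᵢⱼ xᵢxⱼ + e,   e ~ N(0, σ²)

Coding is the affine map of each factor's physical range onto [−1, +1]
via midrange and half-range; it is what makes coefficients comparable
across factors (a flow-rate effect in mL/min and a temperature effect in
°C live on the same scale in coded units). Models are always *fitted* in
the fitting design's own coding; predictions accept physical units and
code internally. Where a verification design shifts a factor's centre
(e.g. a column temperature capped below the nominal optimum), the shifted
centre only moves the coded-0 reference for that design's reporting.

Assumptions worth stating: responses are treated as independent (no
cross-response error correlation — each CMA gets its own model and its own
fit), noise is homoscedastic Gaussian per response, and the quadratic is
taken as the correct mean structure inside the factor ranges. Nothing
mechanistic (plate theory, retention modelling) is implied; the quadratic
is a local response-surface approximation.

## Estimation and term selection

Ordinary least squares via QR decomposition (`numpy.linalg.qr` +
triangular solves); the explicit normal equations are used only as an
independent oracle in the test suite, never in the implementation. Rank
deficiency is detected by pivoted QR and reported with the names of the
collinear terms.

Term selection is one-at-a-time backward elimination at α = 0.05: refit,
drop the removable term with the largest two-sided t-test p-value above
α, repeat. The intercept is never removed, and hierarchy is preserved — a
linear term stays while any retained square or interaction contains its
factor. With zero residual variance the t-test degenerates; p-values are
then defined as 0 for nonzero estimates and 1 for zero estimates, so
noise-free quadratic truths keep all their terms.

## Fit statistics

For n runs and p retained terms:

* R² = 1 − RSS/SS_tot (corrected), adjusted R² = 1 − (RSS/(n−p))/(SS_tot/(n−1)).
* PRESS = Σ (eᵢ/(1−hᵢᵢ))² with leverages from the QR factor; Q² = 1 −
  PRESS/SS_tot. PRESS ≥ RSS pointwise, so Q² ≤ R² always. A leverage of 1
  (a run that determines its own fit) makes PRESS undefined and raises.
  This is the plain leave-one-out Q²; commercial response-surface software
  applies additional corrections for near-saturated models, which are
  intentionally not reproduced.
* Reproducibility = 1 − MS_pure-error/MS_total, with pure error from
  centre replicates only (the only replication the workflow assumes) and
  MS_total = SS_tot/(n−1). Undefined (None) with fewer than two centre
  replicates. This formula was validated against the bundled study's
  printed 4-decimal values from its raw data.
* Regression ANOVA: F = ((SS_tot − RSS)/(p−1)) / (RSS/(n−p)). A
  supplementary lack-of-fit F (residual beyond pure error) is reported
  when pure error is positive, but is not used for term selection.
* Confidence intervals are symmetric t intervals on the coded-unit
  coefficients.

## Design space

The sweet spot counts criteria met at the model-mean prediction on a 2-D
grid (default 101 × 101) over two factors with the rest fixed. The MODR
additionally propagates uncertainty: coefficient vectors are drawn from
N(b̂, Σ̂) per model; with `include_residual` (default on) each draw adds
N(0, σ̂²) so the assurance refers to a *future single measurement*, the
stricter and more defensible reading of operational risk; both modes are
exposed. Draws are independent across responses. The region keeps grid
points whose pass probability is ≥ the assurance level (default 0.99,
n = 10 000 draws, default seed 20200813, echoed in every export).

Covariance sampling uses a symmetric eigendecomposition with eigenvalues
clipped at zero; a materially negative eigenvalue triggers an explicit
warning rather than a silent fix. For grid maps, one set of coefficient
draws per model is shared across grid points: each point's marginal
probability is unchanged, only the spatial correlation of Monte Carlo
noise differs from per-point resampling (the standalone single-point
routine samples fresh).

## Optimization

A coarse grid (default 11 points per factor) over the search ranges is
scored by Monte Carlo pass probability. The probability saturates at 1
over a plateau, so ties are broken by the minimum normalized margin: each
mean prediction's distance from its limit scaled by the limit-to-target
span. When a criterion has no declared target, the default target is
limit ± 10% of the observed response span in the fitting data (toward
the passing side) — targets are a modelling convenience for comparing
margins across criteria with different scales, and the chosen default is
recorded in the result object. The best coarse point is refined by
Nelder–Mead on the margin with a penalty for dropping below the best
observed probability, using one frozen set of draws so the refinement is
deterministic given the seed.

The tie-break's location depends on the target normalization: scaling
margins by the response span (the default) balances run time against the
resolutions differently than scaling by the limits would, and shifts the
flow-rate coordinate of the optimum within the all-criteria plateau. The
acetonitrile and temperature coordinates are stable across both choices.

## Synthetic data

The generator realizes the assumed structure exactly: polynomial truth
surfaces (known coded-unit coefficients) evaluated at a design's coded
levels plus independent N(0, noise_sd) per run. The bundled study
scenario (`celecoxib_truth`) takes its surfaces from fits to the shipped
17-run design and its noise scales from the centre-replicate standard
deviations (R2's three replicates are identical, so its noise is zero).
Every stochastic operation takes an explicit seed; there is no hidden
global state.

What passing the synthetic tests shows: the estimator is unbiased, its
intervals cover at the nominal rate (95% ± binomial error over hundreds
of replicates), PRESS/Q² equal their brute-force counterparts, and the
Monte Carlo machinery is calibrated and monotone. What it does not show:
robustness to drift, heteroscedastic or non-Gaussian noise, model
misspecification, or anything about real chromatographic selectivity.

## Problem sizes and tolerances

The test suite uses reduced grids (41 × 41 or 51 × 51) and 1 000–10 000
Monte Carlo draws; the acceptance script fits the full 17-run dataset and
optimizes with 10 000 draws per evaluation. Agreement with the bundled
study's printed statistics is asserted to ±0.005 (±0.0005 for
reproducibility) because the study's exact retained-term sets are not
published; in practice the backward-eliminated fits reproduce the printed
values — including the regression p-values — to the printed precision.
Published recoveries are matched exactly where the printed concentrations
round cleanly and to ±0.04 elsewhere (the source rounded intermediate
values).

## Known limitations

* One-at-a-time backward elimination is greedy; it is deterministic and
  reproducible but not guaranteed to find the AIC/BIC-optimal subset.
* The MODR grid is 2-D (two free factors, others fixed), matching the
  standard contour-style presentation; a full k-dimensional region is not
  enumerated.
* Q² omits vendor-specific small-sample corrections (see above).
* CSV I/O is deliberately strict (comma-separated, `.` decimal, physical
  units only); coded values are never stored, always recomputed.
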