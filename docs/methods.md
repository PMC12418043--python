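# Methods

## Model

Handgrip strength `Y` at age `t` (one sex) is modelled by the Box–Cox
Cole–Green (BCCG) distribution: with skewness power `L(t)`, median `M(t)`
and coefficient of variation `S(t)`,

    Z = ((Y/M)^L − 1) / (L·S)      (L ≠ 0)
    Z = ln(Y/M) / S                (L = 0)

is standard normal. The centile at rank `p` is the inverse transform at
`z_p = Φ⁻¹(p/100)`. z-values are always computed at full double precision
from the inverse normal CDF, never from rounded tabled constants — the
published percentile cells only reproduce under full-precision z.

Numerical choices in the distribution layer:

* The `L → 0` singularity is removable; the log branch is used for
  `|L| < 1e−7`. Both branches agree to ~1e−9 relative at the switch.
* The BCCG truncation constant (probability mass the Box–Cox transform
  places below zero) is ignored in the density and likelihood, as in
  standard LMS practice; for `S ≤ 0.5` the neglected mass is < 1e−4.
  The sampler draws uniforms inside the valid probability range, i.e. from
  the properly truncated distribution.
* A centile whose argument `1 + L·S·z` is non-positive does not exist for
  that parameter set and raises a domain error rather than returning NaN.

## Fitting

`fit_lms` maximizes the penalized log-likelihood of a one-sex cohort over
the three parameter curves, each parameterized by its values at the
distinct cohort ages (knots) on its link scale — identity for L, log for M
and S, which guarantees valid triples at any age. The requested flexibility
is an effective degrees of freedom (edf) per curve:

* edf = 1 — constant; edf = 2 — exactly linear in age (the null space of
  the curvature penalty); edf equal to the number of ages — unpenalized.
* intermediate edf — knot values with a second-difference penalty
  (first-difference for edf < 2) whose multiplier τ solves
  `tr[(W + τK)⁻¹W] = edf`. `W` holds per-age totals of the expected Fisher
  information per record on the link scale — approximately `2·1.75·S²` for
  L, `2/S²` for log M and `4` for log S in −2·log-likelihood units —
  evaluated at the initial S estimate. Calibrating against raw counts
  instead would leave the curves effectively unpenalized, because the
  likelihood is several times more informative per record about log M than
  a unit-weight least-squares problem.

Optimization is block-coordinate descent over (M, S, L), each block
minimized by bounded L-BFGS-B with tight inner tolerances, so the penalized
deviance is non-increasing across outer iterations; the outer loop stops
when it changes by less than `tol = 1e−6` (max 50 iterations, then a
warning and `converged=False`). Initialization: L = 1, M = per-age sample
medians, S = interquartile-range-based CV (`IQR/(1.349·median)`). Bounds:
L ∈ [−5, 5], S ≥ 1e−4 (the floor a zero-variance cohort is driven to).

Defaults are edf (L, M, S) = (2, 3, 2) — conservative for a five-point age
grid; `select_edf` chooses among candidate configurations by a BIC-type
criterion, `deviance + ln(n)·total edf`, with ties broken by smaller total
edf and then grid order. Age in whole years is used directly as the
continuous covariate (no mid-year offset), matching the integer-age design.
Between knots the fitted curves are evaluated by monotone piecewise-cubic
(PCHIP) interpolation on the link scale, which cannot introduce spurious
wiggles between monotone knot values; tabulated (non-fitted) triples are
interpolated with L, ln M, ln S linear in age. Fitting is deterministic;
all randomness in the pipeline flows through explicit seeds.

## Reference tables and zones

Reference tables tabulate the ranks {3, 10, 35, 50, 65, 90} by default (the
set the published tables realize). Cells are stored at full precision;
2-decimal rounding is purely presentational. The rank-50 column equals M
identically, and centile curves are strictly ordered at every age.

Health Benefit Zones partition the scale per age and sex. The default
`table6` scheme places classification edges at P10/P35/P65/P90 with the
Very Poor band absorbing the open tail below P3 — the banding the published
cut-off table realizes, with nominal masses 10/25/30/25/10 %. The verbal
alternative `section27` (Very Poor < P3, Poor P3–P10, Medium P10–P50, Good
P50–P90, Excellent ≥ P90; nominal 3/7/40/40/10 %) is also implemented: the
two descriptions genuinely conflict, and the package defaults to the
realized one because observed population shares (~32.7 % Medium) match its
30 % nominal Medium mass and not the verbal scheme's 40 %. Classification
is closed-below/open-above at full precision; sub-P3 values are labelled
Very Poor so the classifier is total. Display strings use the published
2-decimal convention (each band's printed lower bound = previous upper
+ 0.01), with half-up rounding.

A regression harness (`reconstruct_and_diff`) recomputes every percentile
cell from a table's stored parameters. With 3-decimal-rounded L and S a
per-cell drift up to ~0.02 kg is legitimate. Running it on the bundled
printed table flags exactly two cells — the girls' P10 values at ages 12
and 13 — which are transposed in print relative to their own parameters
(each recomputed value matches the other row's printed cell to 0.01 kg).
The bundled data keep the printed values; the discrepancy is surfaced, not
silently corrected.

## Back-generation validation

A stratified random holdout (per age × sex stratum,
`round-half-up(fraction·n)` records, default fraction 0.2 — the original
fraction is not on record) is drawn with an explicit seed. Medians per age
are obtained from the full sample ("actual") and the holdout ("fitted"),
by refitting the LMS model on each set (default) or from raw sample medians
(by flag — which of the two the original procedure used is not on record).
Each row is scored with the signed relative error `(actual − fitted)/fitted`;
the fitted-value denominator is the default because it reproduces the
published arithmetic exactly (block averages −0.007 and 0.012 at 3
decimals), while the actual-denominator variant (available by flag) does
not. "MAPE" here is signed; the absolute value is applied only for
interpretation banding: 100·|MAPE| < 10 highly accurate, [10, 20) good,
[20, 50] reasonable, > 50 inaccurate.

## Synthetic cohorts

The generator emulates the study design: 2,970 adolescents in ten
age × sex strata (291–300 each; the published per-age girls' counts sum one
short of the published girls' total, so one stratum is incremented to
reconcile), HGS drawn by inverse-transforming uniforms through the BCCG
quantile at the published per-stratum (L, M, S), and height/weight drawn
log-normally with the published stratum median and a log-scale spread
solved so the IQR matches the published value. Left/right hand maxima are
the absolute value ± a zero-centred half-difference (SD 1 kg, truncated to
keep both positive — the averaging rule is published, asymmetry data are
not), so their mean recovers the absolute value exactly.

What the generator does **not** emulate: the joint distribution of strength
with body size (independent within stratum by default; a rank-coupling knob
exists for demonstrations), school-level clustering, measurement error, or
the ~1 % exclusion process. Passing tests therefore certify the pipeline's
statistical machinery under the published marginals, not claims about the
real population's joint structure.

## Problem sizes and tolerances used in tests

Parameter-recovery properties use 20 seeded replicates of full-design
cohorts (≈1,477 records/sex) and assert medians across seeds: |M̂−M|/M < 2 %
per age, |Ŝ−S|/S < 10 %, |L̂−L| < 0.3. Back-generation end-to-end checks use
three seeds with the default 0.2 holdout and require average |MAPE| < 0.05
per sex. Distributional fidelity uses 10⁵ draws (Kolmogorov–Smirnov
D < 0.01; zone shares within ±0.5 points of nominal). Quantile↔z round
trips hold to 1e−8; the quadrature check integrates the density to 1 within
1e−4.

## Known limitations

* With only five distinct ages the smoothing problem is small; edf above 5
  is meaningless and the spline behaviour between knots is interpolation,
  not data-driven curvature.
* The Fisher-information weights in the edf calibration are frozen at the
  initial S estimate rather than iterated; for the S ranges here the
  resulting edf error is negligible.
* The sample-size planner implements the single-proportion formula
  `n = ceil((z²pq/e²)·D)` only.
* No external-cohort validation is provided; back-generation is an internal
  consistency check and published holdout rows are reproducible only as
  distributional behaviour (the original holdout seed is not on record).
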