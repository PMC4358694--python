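# Methods

## Model and estimands

All analyses operate on pairs (u, v) = (log10 reference, log10 variable) of
positive linear measurements. The logarithm base is 10 throughout: slopes
are base-invariant, and the published intercepts the generator reuses are
consistent with base 10 (e.g. −0.562 + 1.132·log10(689) ≈ log10(448 mm), a
plausible snout–orbit length for the largest skull). Missing values are
handled pairwise complete-case per (variable, reference) pair; specimens
missing the reference value are dropped at load time with a logged count.

**OLS.** slope = Sxy/Sxx, SE² = ((Syy − slope·Sxy)/Sxx)/(n−2), 95% CI with
t(n−2) quantiles, and a two-sided t-test of slope = 1 (the isometric null
for same-dimension linear measurements under geometric similarity).

**SMA.** slope = sign(r)·sqrt(Syy/Sxx). The CI uses the correlation-based
construction B = F(0.95; 1, n−2)(1−r²)/(n−2), CI = slope·(sqrt(B+1) ∓
sqrt(B)); the slope-vs-1 test is the t-test of the Pearson correlation
between (v − u) and (v + u). These are the standard standardized-major-axis
formulas used by the common R implementations; small-sample variants exist,
and pinning these keeps results reproducible.

Estimand note: with residual noise entering v only, the population SMA
slope is b·sqrt(1 + σ²/(b²·Var u)), slightly above the generating b. The
calibration tests therefore check each method's CI against its own
estimand; checking the SMA interval against b would show ~93% coverage by
construction, not by defect.

**Classification.** Positive/negative allometry requires the whole 95% CI
beyond 1; CI endpoints exactly equal to 1 classify as isometric (inclusive
interval). Stars follow the conventional four-level scheme (\* p<0.05 …
\*\*\*\* p<0.0001). Isometric calls with slope-vs-1 p < 0.15 are labelled
*soft* (low power is a plausible explanation), otherwise *hard*; any
threshold in (0.12, 0.22] reproduces the published hard/soft labels
(p = 0.0898 and 0.1199 soft, p ≥ 0.2266 hard), 0.15 is the default and is
exposed as a parameter.

## Subsampling schemes

All schemes draw distinct specimens, without replacement, with n ≥ 3
enforced at the sweep level (the primitives accept n ≥ 2 — and n ≥ 1 for
the random scheme — so that exhaustive enumeration checks at tiny n remain
possible).

* *random*: uniform over the whole series.
* *even length*: the raw-mm reference range is split into n equal-width
  bins, half-open except the last; one specimen uniform per bin; an empty
  bin makes that n infeasible (on realistic size series this caps the
  scheme near n = 10). Bins are computed on raw mm, matching "equal
  divisions of the reference variable"; a log-scale variant would be a
  different design and is not provided.
* *even occupancy*: specimens sorted by reference (ties stable in input
  order) are split at boundaries round(i·N/n), i = 1…n−1, with
  round-half-to-even evaluated on exact rationals; one specimen per bin.
* *adult biased*: the "adult" class is reference ≥ max/2 (closed at the
  boundary, since the juvenile class is defined as strictly less than half
  the maximum); n−1 adults plus exactly one juvenile.

Each replicate uses an independent RNG substream seeded by (master seed,
scheme, CRC-32 of the variable id, n, replicate), so any single replicate
can be reproduced in isolation and a naive reference loop reproduces the
sweep engine exactly.

## Power curves, minimum n, error rates

Default sweep ranges mirror the study conditions: random 3–100, even
occupancy and adult biased 3–20, even length 3–10, at 1,000 replicates per
size (tests and the acceptance script scale replicates down to 200–300,
which keeps Monte-Carlo error on a 95% proportion near ±1.5 points while
keeping the default suite fast). Infeasible sizes are skipped and logged.
Replicates whose subsample is degenerate after pairwise deletion (zero size
variance, fewer than 3 complete pairs) are counted as *failed* and excluded
from the proportion denominator, keeping proportions interpretable; with
realistic series such failures do not occur at n ≥ 3.

The "true" category of a variable is its full-sample classification, never
the generating parameter — the statistic measures agreement with the
whole-series result (synthetic validation tests additionally know the
generator's slope and use it where that is the point of the test). The
minimum sample size is the *first* n at which the proportion of replicates
reproducing an allometric truth reaches 0.95, matching the published worked
example (93% at n = 23, 96% at n = 24 ⇒ minimum 24); a persistent-crossing
variant is available behind a flag. The statistic is undefined for
isometric truths (the null); sweeps that never reach 0.95 are reported
censored as "> sweep max" and are excluded from curve fitting rather than
truncated to their bound, which would fabricate data.

Error rates are definitional transforms of a power curve given the truth:
for allometric truths, false isometry = P(isometric call) and sign error =
P(opposite-sign call); for isometric truths, false allometry =
P(positive) + P(negative). Aggregation across variables is the unweighted
mean with sample SD per subsample size.

## Hyperbolic minimum-n law

y = m/|x−b| (and the offset variant + c) is non-smooth in b at every data
abscissa, so gradient-only fits can stall at the kinks. The fit profiles b
over a 201-point grid spanning (min x, max x), excluding data abscissae —
m (and c) are linear given b — then refines jointly with
`scipy.optimize.least_squares` (tolerances 1e-14), keeping the grid optimum
if refinement does not improve it. For the offset model the basic model's
fitted b is added to the candidate set, which guarantees the nested model
never fits worse. Parameter CIs come from the asymptotic Jacobian
covariance with t(n−p) quantiles. AIC uses the Gaussian
concentrated-likelihood form n·ln(rss/n) + 2k with k = curve parameters + 1
(the residual variance); absolute AIC values therefore differ from values
computed with the full-constant form by an additive shift, but ΔAIC and
Akaike weights — the quantities interpreted — do not.

## Survey comparisons

Group summaries use the arithmetic mean, the midpoint median, and an
inclusive n ≤ 10 proportion. The two-sample KS test uses the asymptotic
two-sided p-value at effective size N_a·N_b/(N_a+N_b)
(`scipy.stats.ks_2samp(method="asymp")`): published integer sample sizes
are heavily tied, where exact small-sample p-values are not defined without
further convention, and the published p-values are consistent with a
standard asymptotic routine.

## Synthetic data: what it emulates and what it does not

The measurement generator *is* the analysis model: reference sizes L are
drawn from a chosen distribution on 29–689 mm (log-uniform by default;
uniform; "adult-skewed", a Beta(α,1)-shaped density on the log-size axis
emulating taphonomic loss of juveniles; or resampling of a user-given
empirical reference vector), and each variable is log-linear with
independent Gaussian log-residuals, with σ set from a target R² via
σ = |b|·sd(u)·sqrt((1−R²)/R²). `alligator_like_spec()` instantiates the 22
published (intercept, slope, R²) triples of the crocodilian cranial series.
Optional 1-mm rounding emulates the field measurement protocol (values
rounding to 0 are clamped to 1 mm).

Deliberately not emulated: covariance between variables (residuals are
independent across variables, whereas real cranial measurements co-vary),
non-normal or heteroscedastic residuals (the real series fails normality
tests), and the empirical series' irregular size-sampling density — the
published minimum-n values reflect that unevenness, so synthetic
random-scheme minimum-n values run slightly lower than the published ones
(e.g. variable 7: ~8–10 synthetic vs 12 published). Passing tests
demonstrate the statistical machinery is correct and calibrated under the
stated conditions, not that any particular real dataset satisfies those
conditions.

The survey generator draws n = round(exp(N(μ, s))) clamped at each group's
published minimum, with μ = ln(median) and s = sqrt(2·ln(mean/median))
moment-matched to the published group means and medians; it reproduces
means, medians and the n ≤ 10 proportions to within sampling error at the
published group counts, but not the exact published maxima or tail shapes.

## Numerical choices and limitations

* t/F quantiles are cached per degrees-of-freedom; F(0.95; 1, d) is the
  squared t(0.975, d) quantile.
* Exactly collinear inputs give zero-width CIs and p-values of 0 or 1 by
  convention; zero-variance or zero-correlation inputs raise degenerate
  errors (flagged per variable, not fatal, in table-level runs).
* Synthetic tables are bit-reproducible given (spec, seed); sweep results
  are bit-reproducible given the master seed.
* Minimum-n is an integer statistic of a stochastic proportion near its
  threshold, so adjacent seeds can shift it by one or two specimens at
  moderate replicate counts; censoring conventions matter near slope 1.
* The hyperbolic model is fitted unweighted, although minimum-n values near
  the asymptote have far larger sampling variance; a weighted or robust
  loss would be a different estimator and is out of scope.
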