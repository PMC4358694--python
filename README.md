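# allompower

Subsampling power analysis for bivariate ontogenetic allometry.

Palaeobiologists (and anyone working with rare taxa) routinely infer
ontogenetic allometry — how the shape of an organism changes with size over
growth — from cross-sectional samples that are far smaller than those
available for common living species. Because isometry (equal proportional
growth) is the usual null hypothesis, small samples produce *false isometry*:
real allometric growth goes undetected simply for lack of statistical power,
which can make fossil taxa look more isometric than living ones.
`allompower` quantifies that effect. It fits log–log allometric lines,
classifies each variable's scaling category, and measures — by Monte-Carlo
subsampling of a full ontogenetic series — how sample size and the
distribution of specimens along the size axis drive error rates and the
minimum sample needed for a reliable conclusion.

## The model

Every variable `y` (a linear measurement, mm) is regressed against a
reference datum `x` (basal skull length in the crocodilian dataset the
package is patterned on) on log scale:

    log10 y = a + b · log10 x + ε,    ε ~ N(0, σ²)

with the slope `b` fitted by ordinary least squares (OLS) and by standardized
major axis (SMA, slope = sign(r)·s_y/s_x). A variable is **positively
allometric** when the 95% CI of `b` lies above 1, **negatively allometric**
below 1, and **isometric** when the CI includes 1; isometric calls are
annotated *hard* (robust) or *soft* (plausibly a power artefact, small
slope-vs-1 p-value).

Four subsampling schemes (uniform random; even-length size bins; even-occupancy
size bins; adult-biased, n−1 large specimens plus one juvenile) are replicated
at every subsample size n, giving per-category *power curves*, the
**minimum sample size** (smallest n at which ≥95% of replicates reproduce the
full-sample category), and false-allometry / false-isometry / sign-error rate
curves. The minimum-n-vs-slope relation is modelled by nested hyperbolas

    y = m / |x − b|        and        y = m / |x − b| + c

fitted by profiled least squares and compared with AIC and Akaike weights
(the vertical asymptote `b` sits just off the isometric slope 1). A survey
module summarises published sample-size distributions per taxon group and
compares them with two-sample Kolmogorov–Smirnov tests. A synthetic-data
generator reproduces the full study conditions (22 cranial variables with
published intercepts, slopes and R², reference sizes 29–689 mm; right-skewed
survey sample sizes), so the entire pipeline is testable end to end.

## Worked example

```python
import allompower as ap

table = ap.simulate_dataset(ap.alligator_like_spec(), 108, seed=42)
results = ap.AllometryModel(table, method="ols").fit()
print(results.summary().head(5).round(3).to_string(index=False))

curve = ap.run_sweep(table, "7", "ols", "random", range(3, 101), reps=200, seed=42)
print("min n for variable 7:",
      ap.min_sample_for_agreement(curve, results.true_categories()["7"]))
print(curve.proportions().loc[[5, 10, 15]].round(3).to_string())
```

prints

```
variable   n    r2  intercept  slope  ci_low  ci_high trend  sig  p_vs_1
      23 108 0.920     -0.377  0.635   0.599    0.671     - ****     0.0
      10 108 0.964     -0.066  0.664   0.639    0.688     - ****     0.0
       9 108 0.978     -0.067  0.720   0.699    0.741     - ****     0.0
      15 108 0.945     -0.555  0.792   0.755    0.828     - ****     0.0
      13 108 0.970     -0.831  0.899   0.868    0.929     - ****     0.0
min n for variable 7: 10
    p_positive  p_negative  p_isometric  n_failed  reps
n
5        0.560         0.0        0.440         0   200
10       0.965         0.0        0.035         0   200
15       0.995         0.0        0.005         0   200
```

Variable 7 (snout–orbit length, generating slope 1.132) is strongly
positively allometric in the full series, yet at n = 5 almost half of the
random subsamples call it isometric; ten specimens are needed before 95% of
replicates recover the allometry. The same machinery is available from the
shell:

```bash
allompower simulate --n 108 --seed 42 --out table.csv
allompower sweep --input table.csv --reference 6 --method ols \
    --scheme random --reps 1000 --seed 42 --outdir sweep_out
allompower fit-hyperbola --input sweep_out/min_sample.csv --out fits.csv
```

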