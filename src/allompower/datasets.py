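"""Published reference values used to parameterise the synthetic generators.

Two small printed tables are carried here as plain data:

* the full-sample OLS allometry of 22 cranial measurements of
  *Alligator mississippiensis* against basal skull length (variable "6"),
  including the minimum subsample size at which 95% of random-subsample
  replicates reproduced the full-sample scaling category;
* the four-group summary of sample sizes used in published intraspecific
  allometry studies (invertebrate/vertebrate x extant/extinct).

These published coefficients define the "alligator-like" synthetic study
conditions and serve as fixed inputs for the minimum-sample-size curve
reanalysis; they are data, not fitted output of this package.
"""

from __future__ import annotations

#: Reference datum of the cranial series: basal skull length.
REFERENCE_VARIABLE = "6"

#: Size range (mm) of the reference datum across the measured series.
REFERENCE_RANGE_MM = (29.0, 689.0)

#: Number of specimens in the measured cranial series.
N_SPECIMENS = 108

#: Full-sample OLS fits per variable: R^2, intercept and slope of
#: log10(variable) on log10(basal skull length), the 95% CI of the slope,
#: the scaling trend ("+", "-", or "iso") and the minimum random-subsample
#: size for 95% agreement with the full-sample trend.  ``min_n_random`` is
#: None when the trend is isometric (the statistic is undefined for the
#: null category) or when 95% agreement was not reached by n = 100
#: (censored; see ``censored``).
ALLIGATOR_CRANIAL_OLS = (
    {"variable": "23", "r2": 0.928, "intercept": -0.408, "slope": 0.651, "ci_low": 0.616, "ci_high": 0.685, "trend": "-", "min_n_random": 7, "censored": False},
    {"variable": "10", "r2": 0.969, "intercept": -0.073, "slope": 0.666, "ci_low": 0.643, "ci_high": 0.689, "trend": "-", "min_n_random": 6, "censored": False},
    {"variable": "9", "r2": 0.981, "intercept": -0.103, "slope": 0.737, "ci_low": 0.717, "ci_high": 0.757, "trend": "-", "min_n_random": 6, "censored": False},
    {"variable": "15", "r2": 0.951, "intercept": -0.541, "slope": 0.784, "ci_low": 0.749, "ci_high": 0.818, "trend": "-", "min_n_random": 15, "censored": False},
    {"variable": "13", "r2": 0.974, "intercept": -0.860, "slope": 0.916, "ci_low": 0.887, "ci_high": 0.944, "trend": "-", "min_n_random": 43, "censored": False},
    {"variable": "5", "r2": 0.990, "intercept": -0.335, "slope": 0.946, "ci_low": 0.922, "ci_high": 0.969, "trend": "-", "min_n_random": 61, "censored": False},
    {"variable": "22", "r2": 0.977, "intercept": -0.571, "slope": 0.959, "ci_low": 0.931, "ci_high": 0.988, "trend": "-", "min_n_random": 98, "censored": False},
    {"variable": "12", "r2": 0.976, "intercept": -0.986, "slope": 0.969, "ci_low": 0.940, "ci_high": 0.998, "trend": "-", "min_n_random": None, "censored": True},
    {"variable": "14", "r2": 0.993, "intercept": -0.244, "slope": 0.991, "ci_low": 0.974, "ci_high": 1.007, "trend": "iso", "min_n_random": None, "censored": False},
    {"variable": "17", "r2": 0.988, "intercept": -0.445, "slope": 0.996, "ci_low": 0.975, "ci_high": 1.017, "trend": "iso", "min_n_random": None, "censored": False},
    {"variable": "3", "r2": 0.993, "intercept": -0.379, "slope": 1.003, "ci_low": 0.987, "ci_high": 1.020, "trend": "iso", "min_n_random": None, "censored": False},
    {"variable": "8", "r2": 0.994, "intercept": -0.567, "slope": 1.010, "ci_low": 0.994, "ci_high": 1.025, "trend": "iso", "min_n_random": None, "censored": False},
    {"variable": "4", "r2": 0.990, "intercept": -0.327, "slope": 1.017, "ci_low": 0.997, "ci_high": 1.038, "trend": "iso", "min_n_random": None, "censored": False},
    {"variable": "2", "r2": 0.994, "intercept": -0.491, "slope": 1.025, "ci_low": 1.010, "ci_high": 1.040, "trend": "+", "min_n_random": 77, "censored": False},
    {"variable": "19", "r2": 0.986, "intercept": -0.746, "slope": 1.033, "ci_low": 1.009, "ci_high": 1.057, "trend": "+", "min_n_random": 95, "censored": False},
    {"variable": "11", "r2": 0.977, "intercept": -1.247, "slope": 1.043, "ci_low": 1.012, "ci_high": 1.073, "trend": "+", "min_n_random": 95, "censored": False},
    {"variable": "1", "r2": 0.991, "intercept": -0.687, "slope": 1.052, "ci_low": 1.032, "ci_high": 1.072, "trend": "+", "min_n_random": 36, "censored": False},
    {"variable": "16", "r2": 0.981, "intercept": -0.702, "slope": 1.054, "ci_low": 1.026, "ci_high": 1.082, "trend": "+", "min_n_random": 64, "censored": False},
    {"variable": "20", "r2": 0.982, "intercept": -1.218, "slope": 1.066, "ci_low": 1.038, "ci_high": 1.093, "trend": "+", "min_n_random": 53, "censored": False},
    {"variable": "18", "r2": 0.991, "intercept": -0.970, "slope": 1.089, "ci_low": 1.070, "ci_high": 1.109, "trend": "+", "min_n_random": 18, "censored": False},
    {"variable": "21", "r2": 0.984, "intercept": -1.133, "slope": 1.100, "ci_low": 1.073, "ci_high": 1.127, "trend": "+", "min_n_random": 35, "censored": False},
    {"variable": "7", "r2": 0.995, "intercept": -0.562, "slope": 1.132, "ci_low": 1.117, "ci_high": 1.147, "trend": "+", "min_n_random": 12, "censored": False},
)

#: Published 95% CI of the vertical-asymptote parameter b of the basic
#: hyperbolic minimum-n model fitted to the OLS (slope, min-n) point set.
ALLIGATOR_HYPERBOLA_OLS_B_CI = (0.985, 0.999)

#: Published AIC of (basic hyperbola, offset hyperbola) per point set.
ALLIGATOR_HYPERBOLA_AIC = {
    "combined": (251.087, 252.855),
    "rma": (133.885, 135.698),
    "ols": (122.531, 124.512),
}

#: Delta-AIC derived from :data:`ALLIGATOR_HYPERBOLA_AIC`.  Note: the
#: published delta row lists 1.183 for the RMA pair, a digit transposition of
#: the 1.813 implied by the published AICs; only 1.813 is consistent with the
#: published Akaike weight 0.712.
ALLIGATOR_HYPERBOLA_DELTA_AIC = {
    name: (0.0, round(pair[1] - pair[0], 3))
    for name, pair in ALLIGATOR_HYPERBOLA_AIC.items()
}

#: Published Akaike weights matching :data:`ALLIGATOR_HYPERBOLA_DELTA_AIC`.
ALLIGATOR_HYPERBOLA_WEIGHTS = {
    "combined": (0.708, 0.292),
    "rma": (0.712, 0.288),
    "ols": (0.729, 0.271),
}

#: Sample-size distributions of published intraspecific-allometry studies,
#: per taxon group and preservation status: count of samples, smallest and
#: largest published n, arithmetic mean and median n, and the proportion of
#: samples with n <= 10.
SURVEY_GROUPS = (
    {"group": "invertebrate", "status": "extant", "count": 178, "min": 6, "max": 1449, "mean": 72.3, "median": 32.5, "prop_n_le_10": 0.056},
    {"group": "vertebrate", "status": "extant", "count": 169, "min": 6, "max": 984, "mean": 75.7, "median": 40.0, "prop_n_le_10": 0.030},
    {"group": "invertebrate", "status": "extinct", "count": 119, "min": 3, "max": 733, "mean": 39.7, "median": 19.0, "prop_n_le_10": 0.201},
    {"group": "vertebrate", "status": "extinct", "count": 76, "min": 4, "max": 110, "mean": 21.4, "median": 14.0, "prop_n_le_10": 0.347},
)
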