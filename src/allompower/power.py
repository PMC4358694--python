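"""Replicate subsampling sweeps, power curves, minimum-n and error-rate statistics.

For one variable, one line-fitting method and one subsampling scheme, a sweep
draws ``reps`` independent subsamples at every size ``n`` in a range, fits the
log-log line on each, classifies the scaling category, and tallies the
outcomes into a :class:`PowerCurve` -- the proportion of replicates calling
each category as a function of n (an "allometric power plot").

From a power curve and the full-sample ("true") category follow:

* the minimum-sample-size statistic -- the smallest n at which the true
  category is reproduced by at least 95% of replicates (first crossing);
* error-rate curves -- false isometry (calling the allometric true category
  isometric; a Type-II-like error), false allometry (calling a true isometry
  allometric; Type-I-like) and sign error (allometry of the wrong direction).

The "true" category is always the full-sample classification, never a
generating parameter: the whole-series result is the reference point the
subsamples are judged against.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import (
    ConfigurationError,
    DegenerateDataError,
    SampleSizeError,
    ValidationError,
)
from .regression import (
    CATEGORIES,
    DEFAULT_SOFT_ISO_P,
    AllometryModel,
    classify,
    fit_pair,
)
from .subsampling import SCHEMES, draw, feasible, substream
from .tables import MeasurementTable, log_transform

logger = logging.getLogger(__name__)

#: Default sweep ranges per scheme (inclusive ends): the random scheme sweeps
#: 3-100; the binned and adult-biased schemes cannot go far before bins empty
#: out, so they sweep 3-20 (occupancy, adult) and 3-10 (length).
DEFAULT_N_RANGES = {
    "random": range(3, 101),
    "even_occupancy": range(3, 21),
    "adult_biased": range(3, 21),
    "even_length": range(3, 11),
}

#: Replicates per subsample size.
DEFAULT_REPS = 1000


@dataclass
class PowerCurve:
    """Replicate tallies per subsample size for one (variable, method, scheme).

    ``counts`` is indexed by n with columns positive, negative, isometric,
    failed, reps; ``skipped`` lists sweep sizes that were infeasible for the
    scheme.  Proportions are taken over non-failed replicates.
    """

    variable_id: str
    method: str
    scheme: str
    counts: pd.DataFrame
    skipped: tuple = ()

    def proportions(self) -> pd.DataFrame:
        """p_positive, p_negative, p_isometric per n (failed excluded)."""
        ok = (self.counts["reps"] - self.counts["failed"]).astype(float)
        out = pd.DataFrame(index=self.counts.index)
        for cat in CATEGORIES:
            out[f"p_{cat}"] = np.where(ok > 0, self.counts[cat] / ok, np.nan)
        out["n_failed"] = self.counts["failed"]
        out["reps"] = self.counts["reps"]
        return out

    def proportion(self, category: str) -> pd.Series:
        if category not in CATEGORIES:
            raise ConfigurationError(f"unknown category {category!r}")
        return self.proportions()[f"p_{category}"]


def run_sweep(
    table: MeasurementTable,
    variable_id,
    method: str = "ols",
    scheme: str = "random",
    n_range=None,
    reps: int = DEFAULT_REPS,
    seed: int = 0,
    base: float = 10.0,
) -> PowerCurve:
    """Monte-Carlo subsampling sweep for one variable.

    Subsamples are drawn on the raw reference values (bin edges in mm); fits
    use the log-transformed pairwise-complete pairs within each subsample.
    Degenerate subsamples (zero size variance, too few complete pairs) are
    counted as failed.  Infeasible sweep sizes are recorded in ``skipped``,
    not fatal.  Deterministic given ``seed``.
    """
    if scheme not in SCHEMES:
        raise ConfigurationError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    if reps < 1:
        raise ConfigurationError(f"reps must be >= 1, got {reps}")
    if n_range is None:
        n_range = DEFAULT_N_RANGES[scheme]
    logt = log_transform(table, base)
    ref_raw = table.reference_values()
    U = logt.data[logt.reference_id].to_numpy(dtype=float)
    V = logt.data[variable_id].to_numpy(dtype=float)

    rows = []
    skipped = []
    for n in n_range:
        if not feasible(scheme, ref_raw, n):
            skipped.append(int(n))
            logger.info(
                "scheme %s infeasible at n=%d for variable %r; skipped",
                scheme, n, variable_id,
            )
            continue
        tally = dict.fromkeys(CATEGORIES, 0)
        failed = 0
        for rep in range(reps):
            rng = substream(seed, scheme, variable_id, n, rep)
            idx = draw(scheme, ref_raw, n, rng)
            uu = U[idx]
            vv = V[idx]
            mask = np.isfinite(uu) & np.isfinite(vv)
            try:
                res = fit_pair(uu[mask], vv[mask], method)
            except (DegenerateDataError, SampleSizeError):
                failed += 1
                continue
            tally[classify(res).category] += 1
        rows.append({"n": int(n), **tally, "failed": failed, "reps": reps})
    counts = pd.DataFrame(rows).set_index("n") if rows else pd.DataFrame(
        columns=[*CATEGORIES, "failed", "reps"]
    )
    return PowerCurve(str(variable_id), method, scheme, counts, tuple(skipped))


@dataclass
class MinSampleResult:
    """Minimum subsample size reproducing the full-sample category in >= level.

    ``applicable`` is False for isometric truths (the statistic is undefined
    for the null category); ``censored`` is True when the level was never
    reached within the sweep, in which case the result reads "> sweep_max".
    """

    variable_id: str
    method: str
    scheme: str
    true_category: str
    min_n: int | None
    censored: bool
    applicable: bool
    sweep_max: int | None
    level: float

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        if not self.applicable:
            return "n/a"
        if self.censored:
            return f">{self.sweep_max}"
        return str(self.min_n)


def min_sample_for_agreement(
    curve: PowerCurve,
    true_category: str,
    level: float = 0.95,
    persistent: bool = False,
) -> MinSampleResult:
    """First sweep size at which >= ``level`` of replicates call ``true_category``.

    The default is the literal first crossing; ``persistent=True`` instead
    requires the proportion to stay at or above the level for all larger
    sweep sizes (a sensitivity variant).
    """
    if true_category not in CATEGORIES:
        raise ConfigurationError(f"unknown category {true_category!r}")
    common = dict(
        variable_id=curve.variable_id,
        method=curve.method,
        scheme=curve.scheme,
        true_category=true_category,
        level=level,
    )
    if true_category == "isometric":
        return MinSampleResult(
            **common, min_n=None, censored=False, applicable=False, sweep_max=None
        )
    props = curve.proportion(true_category).dropna()
    if props.empty:
        raise ValidationError("power curve has no usable sweep sizes")
    sweep_max = int(props.index.max())
    hit = props[props >= level]
    if persistent and not hit.empty:
        ok = [n for n in hit.index if (props.loc[n:] >= level).all()]
        hit = props.loc[ok] if ok else props.iloc[0:0]
    if hit.empty:
        return MinSampleResult(
            **common, min_n=None, censored=True, applicable=True, sweep_max=sweep_max
        )
    return MinSampleResult(
        **common,
        min_n=int(hit.index[0]),
        censored=False,
        applicable=True,
        sweep_max=sweep_max,
    )


@dataclass
class ErrorRateCurve:
    """False-allometry / false-isometry / sign-error rates per sweep size.

    For an aggregate curve the frame also carries ``*_sd`` columns (sample SD
    across variables).
    """

    label: str
    method: str
    scheme: str
    rates: pd.DataFrame


_ERROR_COLUMNS = ("false_allometry", "false_isometry", "sign_error")


def error_rates(curve: PowerCurve, true_category: str) -> ErrorRateCurve:
    """Definitional error rates given the full-sample category.

    Allometric truth: false isometry = P(isometric), sign error = P(opposite
    allometry), false allometry = 0.  Isometric truth: false allometry =
    P(positive) + P(negative), the other two = 0.
    """
    if true_category not in CATEGORIES:
        raise ConfigurationError(f"unknown category {true_category!r}")
    p = curve.proportions()
    out = pd.DataFrame(index=p.index)
    if true_category == "isometric":
        out["false_allometry"] = p["p_positive"] + p["p_negative"]
        out["false_isometry"] = 0.0
        out["sign_error"] = 0.0
    else:
        opposite = "negative" if true_category == "positive" else "positive"
        out["false_allometry"] = 0.0
        out["false_isometry"] = p["p_isometric"]
        out["sign_error"] = p[f"p_{opposite}"]
    return ErrorRateCurve(curve.variable_id, curve.method, curve.scheme, out)


def aggregate_error_rates(curves: list) -> ErrorRateCurve:
    """Unweighted mean and sample SD of error rates across variables, per n."""
    if not curves:
        raise ValidationError("need at least one error-rate curve")
    grid = curves[0].rates.index
    for c in curves[1:]:
        if not c.rates.index.equals(grid):
            raise ValidationError("error-rate curves are on mismatched n grids")
    out = pd.DataFrame(index=grid)
    for col in _ERROR_COLUMNS:
        stacked = np.column_stack([c.rates[col].to_numpy() for c in curves])
        out[col] = stacked.mean(axis=1)
        out[f"{col}_sd"] = stacked.std(axis=1, ddof=1) if stacked.shape[1] > 1 else 0.0
    return ErrorRateCurve(
        "aggregate", curves[0].method, curves[0].scheme, out
    )


class SubsamplingPowerAnalysis:
    """Full subsampling experiment over every non-reference variable of a table.

    Fits the whole series first (the "truth"), then sweeps every variable
    under one scheme and method, and derives minimum-sample-size results and
    error-rate curves.  ``run()`` returns a :class:`PowerAnalysisResults`.
    """

    def __init__(
        self,
        table: MeasurementTable,
        method: str = "ols",
        scheme: str = "random",
        n_range=None,
        reps: int = DEFAULT_REPS,
        seed: int = 0,
        level: float = 0.95,
        base: float = 10.0,
        soft_iso_p: float = DEFAULT_SOFT_ISO_P,
    ):
        self.table = table
        self.method = "sma" if method.lower() == "rma" else method.lower()
        self.scheme = scheme
        self.n_range = list(DEFAULT_N_RANGES[scheme] if n_range is None else n_range)
        self.reps = reps
        self.seed = seed
        self.level = level
        self.base = base
        self.soft_iso_p = soft_iso_p

    def run(self) -> "PowerAnalysisResults":
        full = AllometryModel(
            self.table, self.method, self.base, self.soft_iso_p
        ).fit()
        truths = full.true_categories()
        curves = {}
        min_samples = []
        err = {}
        for var in self.table.non_reference_ids:
            if var not in truths:
                logger.warning(
                    "variable %r failed the full-sample fit; excluded from sweep", var
                )
                continue
            curve = run_sweep(
                self.table, var, self.method, self.scheme,
                self.n_range, self.reps, self.seed, self.base,
            )
            curves[var] = curve
            min_samples.append(
                min_sample_for_agreement(curve, truths[var], self.level)
            )
            err[var] = error_rates(curve, truths[var])
        aggregate = aggregate_error_rates(list(err.values())) if err else None
        return PowerAnalysisResults(self, full, curves, min_samples, err, aggregate)


class PowerAnalysisResults:
    """Results of a :class:`SubsamplingPowerAnalysis` run."""

    def __init__(self, analysis, full_fit, curves, min_samples, error, aggregate_error):
        self.analysis = analysis
        self.full_fit = full_fit
        self.curves = curves
        self.min_samples = list(min_samples)
        self.error = error
        self.aggregate_error = aggregate_error

    def power_table(self) -> pd.DataFrame:
        """Long-format power curves (the data behind the power plots)."""
        frames = []
        for var, curve in self.curves.items():
            p = curve.proportions().reset_index()
            p.insert(0, "variable", var)
            p.insert(1, "method", curve.method)
            p.insert(2, "scheme", curve.scheme)
            frames.append(p)
        return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()

    def min_sample_table(self) -> pd.DataFrame:
        """Minimum-sample-size results with the full-sample slope per variable."""
        rows = []
        for ms in self.min_samples:
            res = self.full_fit.results.get(ms.variable_id)
            rows.append(
                {
                    "variable": ms.variable_id,
                    "method": ms.method,
                    "scheme": ms.scheme,
                    "slope": res.slope if res else np.nan,
                    "true_category": ms.true_category,
                    "min_n": ms.min_n,
                    "censored": ms.censored,
                    "applicable": ms.applicable,
                    "sweep_max": ms.sweep_max,
                }
            )
        return pd.DataFrame(rows)

    def error_rate_table(self) -> pd.DataFrame:
        """Long-format per-variable and aggregate error-rate curves."""
        frames = []
        for var, c in self.error.items():
            f = c.rates.reset_index()
            f.insert(0, "variable", var)
            frames.append(f)
        if self.aggregate_error is not None:
            f = self.aggregate_error.rates.reset_index()
            f.insert(0, "variable", "aggregate")
            frames.append(f)
        return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()

    def scaling_points(self) -> list:
        """(slope, min-n) points for the hyperbolic minimum-n model."""
        from .hyperbola import ScalingPoint

        points = []
        for ms in self.min_samples:
            if not ms.applicable:
                continue
            slope = self.full_fit.results[ms.variable_id].slope
            if ms.censored:
                points.append(ScalingPoint(slope, float(ms.sweep_max), censored=True))
            else:
                points.append(ScalingPoint(slope, float(ms.min_n)))
        return points
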