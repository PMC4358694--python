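"""Bivariate line fitting on log-log data and categorical scaling classification.

Two line-fitting conventions are supported:

* **OLS** -- ordinary least squares of log(variable) on log(reference),
  minimising vertical residuals; slope = Sxy/Sxx.
* **SMA** -- standardized (reduced) major axis, slope = sign(r) sqrt(Syy/Sxx),
  symmetric in the two variables.  The slope CI uses the standard
  correlation-based construction B = F(0.95; 1, n-2)(1-r^2)/(n-2),
  CI = slope (sqrt(B+1) -/+ sqrt(B)), and the slope-vs-1 test is the t-test
  of the Pearson correlation between (v - u) and (v + u).

Each fitted variable is classified against geometric similarity (isometry,
log-log slope 1): positively allometric when the 95% CI of the slope lies
above 1, negatively allometric when it lies below 1, isometric otherwise.
Isometric results are annotated "hard" (robust: large p for the slope-vs-1
test) or "soft" (plausibly a power artefact: small p without CI exclusion).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import math

import numpy as np
import pandas as pd
from scipy import special

from .exceptions import ConfigurationError, DegenerateDataError, SampleSizeError
from .tables import LogTable, MeasurementTable, log_transform

METHODS = ("ols", "sma")

CATEGORIES = ("positive", "negative", "isometric")

#: Default p-value threshold separating soft from hard isometry.
DEFAULT_SOFT_ISO_P = 0.15

_STAR_LEVELS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


@lru_cache(maxsize=None)
def _t975(df: int) -> float:
    """97.5% quantile of Student's t with ``df`` degrees of freedom."""
    return float(special.stdtrit(df, 0.975))


def _p_two_sided(t: float, df: int) -> float:
    return float(2.0 * special.stdtr(df, -abs(t)))


def significance_stars(p: float) -> str:
    """Conventional 4-level star grade: * p<0.05 up to **** p<0.0001."""
    for level, stars in _STAR_LEVELS:
        if p < level:
            return stars
    return ""


@dataclass(frozen=True)
class RegressionResult:
    """One fitted log-log line: estimates, 95% slope CI and slope-vs-1 test."""

    method: str
    n: int
    slope: float
    intercept: float
    r2: float
    ci_low: float
    ci_high: float
    p_vs_1: float


@dataclass(frozen=True)
class ScalingCategory:
    """Categorical scaling call with isometry subtype and significance stars."""

    category: str  # positive | negative | isometric
    iso_subtype: str  # hard | soft | not-applicable
    stars: str


def _sums(u, v):
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.ndim != 1:
        raise ConfigurationError("u and v must be 1-d arrays of equal length")
    n = u.size
    if n < 3:
        raise SampleSizeError(f"need at least 3 complete pairs, got {n}")
    um = u.mean()
    vm = v.mean()
    du = u - um
    dv = v - vm
    sxx = float(du @ du)
    syy = float(dv @ dv)
    sxy = float(du @ dv)
    return u, v, n, um, vm, sxx, syy, sxy


def fit_ols(u, v) -> RegressionResult:
    """Ordinary least squares of v on u with 95% slope CI and slope-vs-1 test."""
    u, v, n, um, vm, sxx, syy, sxy = _sums(u, v)
    if sxx <= 0:
        raise DegenerateDataError("zero variance in the reference values")
    slope = sxy / sxx
    intercept = vm - slope * um
    # syy == 0 means an exactly flat line fits perfectly
    r2 = min(1.0, sxy * sxy / (sxx * syy)) if syy > 0 else 1.0
    se = math.sqrt(max((syy - slope * sxy) / sxx, 0.0) / (n - 2))
    tq = _t975(n - 2)
    if se > 0:
        p = _p_two_sided((slope - 1.0) / se, n - 2)
    else:
        p = 1.0 if slope == 1.0 else 0.0
    return RegressionResult(
        "ols", n, slope, intercept, r2, slope - tq * se, slope + tq * se, p
    )


def fit_sma(u, v) -> RegressionResult:
    """Standardized major axis fit of (u, v) with CI and slope-vs-1 test."""
    u, v, n, um, vm, sxx, syy, sxy = _sums(u, v)
    if sxx <= 0:
        raise DegenerateDataError("zero variance in the reference values")
    if syy <= 0:
        raise DegenerateDataError("zero variance in the dependent values")
    r = sxy / math.sqrt(sxx * syy)
    if r == 0:
        raise DegenerateDataError("zero correlation: the SMA slope sign is undefined")
    slope = math.copysign(math.sqrt(syy / sxx), r)
    intercept = vm - slope * um
    r2 = min(1.0, r * r)
    # F(0.95; 1, n-2) equals the squared 97.5% t quantile
    tq = _t975(n - 2)
    B = (tq * tq) * (1.0 - r2) / (n - 2)
    lo = slope * (math.sqrt(B + 1.0) - math.sqrt(B))
    hi = slope * (math.sqrt(B + 1.0) + math.sqrt(B))
    ci_low, ci_high = (lo, hi) if slope > 0 else (hi, lo)
    # slope-vs-1 test: correlation between v - u and v + u
    d = v - u
    s = v + u
    vard = float(np.var(d))
    vars_ = float(np.var(s))
    if vard == 0:
        p = 1.0  # v = u + const exactly: slope exactly 1
    elif vars_ == 0:
        p = 0.0  # v = -u + const exactly: slope exactly -1
    else:
        rp = float(np.cov(d, s, ddof=1)[0, 1]) / math.sqrt(
            float(np.var(d, ddof=1)) * float(np.var(s, ddof=1))
        )
        if rp * rp >= 1.0:
            p = 0.0
        else:
            p = _p_two_sided(rp * math.sqrt((n - 2) / (1.0 - rp * rp)), n - 2)
    return RegressionResult("sma", n, slope, intercept, r2, ci_low, ci_high, p)


def fit_pair(u, v, method: str) -> RegressionResult:
    """Dispatch to :func:`fit_ols` or :func:`fit_sma`."""
    method = method.lower()
    if method == "ols":
        return fit_ols(u, v)
    if method in ("sma", "rma"):
        return fit_sma(u, v)
    raise ConfigurationError(f"unknown method {method!r}; expected one of {METHODS}")


def classify(result: RegressionResult, soft_iso_p: float = DEFAULT_SOFT_ISO_P) -> ScalingCategory:
    """Scaling category from the slope CI; CI endpoints equal to 1 are isometric."""
    if result.ci_low > 1.0:
        category = "positive"
    elif result.ci_high < 1.0:
        category = "negative"
    else:
        category = "isometric"
    stars = significance_stars(result.p_vs_1)
    if category == "isometric":
        subtype = "soft" if result.p_vs_1 < soft_iso_p else "hard"
    else:
        subtype = "not-applicable"
    return ScalingCategory(category, subtype, stars)


@dataclass(frozen=True)
class VariableFit:
    """Per-variable outcome of :func:`regress_all`; ``error`` set when degenerate."""

    variable_id: str
    result: RegressionResult | None
    category: ScalingCategory | None
    error: str | None = None


def regress_all(
    table,
    method: str = "ols",
    base: float = 10.0,
    soft_iso_p: float = DEFAULT_SOFT_ISO_P,
) -> list:
    """Fit every non-reference variable against the reference datum.

    Accepts a raw :class:`MeasurementTable` (log-transformed internally) or a
    prepared :class:`LogTable`.  Pairs are complete-case per variable.
    Degenerate variables are returned as flagged entries, not raised.
    """
    logt = table if isinstance(table, LogTable) else log_transform(table, base)
    fits = []
    for var in logt.non_reference_ids:
        u, v = logt.pair(var)
        try:
            res = fit_pair(u, v, method)
        except (DegenerateDataError, SampleSizeError) as exc:
            fits.append(VariableFit(var, None, None, str(exc)))
            continue
        fits.append(VariableFit(var, res, classify(res, soft_iso_p)))
    return fits


_TREND_SYMBOL = {"positive": "+", "negative": "-"}


class AllometryModel:
    """Log-log allometry of every variable in a table against its reference datum.

    Parameters
    ----------
    table
        A :class:`MeasurementTable` (raw mm values).
    method
        "ols" or "sma".
    base
        Logarithm base for the transformation (slopes are base-invariant;
        intercepts are reported in this base).
    soft_iso_p
        p-value threshold separating soft from hard isometry.
    """

    def __init__(self, table: MeasurementTable, method: str = "ols",
                 base: float = 10.0, soft_iso_p: float = DEFAULT_SOFT_ISO_P):
        if not isinstance(table, MeasurementTable):
            raise TypeError("AllometryModel expects a MeasurementTable")
        method = method.lower()
        if method == "rma":
            method = "sma"
        if method not in METHODS:
            raise ConfigurationError(f"unknown method {method!r}")
        self.table = table
        self.method = method
        self.base = base
        self.soft_iso_p = soft_iso_p

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, reference: str, **kwargs) -> "AllometryModel":
        """Build from a specimen x variable DataFrame of raw mm values."""
        return cls(MeasurementTable(frame, reference), **kwargs)

    def fit(self) -> "AllometryResults":
        fits = regress_all(self.table, self.method, self.base, self.soft_iso_p)
        return AllometryResults(self, fits)


class AllometryResults:
    """Fitted allometry of a table: per-variable estimates and scaling calls."""

    def __init__(self, model: AllometryModel, fits: list):
        self.model = model
        self.fits = list(fits)
        self.results = {f.variable_id: f.result for f in fits if f.result is not None}
        self.categories = {f.variable_id: f.category for f in fits if f.category is not None}
        self.failures = {f.variable_id: f.error for f in fits if f.error is not None}

    def __getitem__(self, variable_id: str) -> VariableFit:
        for f in self.fits:
            if f.variable_id == variable_id:
                return f
        raise KeyError(variable_id)

    def true_categories(self) -> dict:
        """Full-sample scaling category per variable (the subsampling 'truth')."""
        return {v: c.category for v, c in self.categories.items()}

    def summary(self) -> pd.DataFrame:
        """One row per variable, mirroring the conventional report layout.

        Columns: variable, n, r2, intercept, slope, ci_low, ci_high, trend
        ("+", "-", "h. iso", "s. iso" or "failed"), sig (stars for allometric
        trends, the slope-vs-1 p-value for isometric ones), p_vs_1.
        """
        rows = []
        for f in self.fits:
            if f.result is None:
                rows.append({"variable": f.variable_id, "trend": "failed",
                             "sig": "", "error": f.error})
                continue
            res, cat = f.result, f.category
            if cat.category == "isometric":
                trend = f"{cat.iso_subtype[0]}. iso"
                sig = f"{res.p_vs_1:.4f}"
            else:
                trend = _TREND_SYMBOL[cat.category]
                sig = cat.stars
            rows.append(
                {
                    "variable": f.variable_id,
                    "n": res.n,
                    "r2": res.r2,
                    "intercept": res.intercept,
                    "slope": res.slope,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "trend": trend,
                    "sig": sig,
                    "p_vs_1": res.p_vs_1,
                }
            )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.summary().to_csv(path, index=False)
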