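"""Hyperbolic models of minimum sample size as a function of scaling slope.

The minimum number of specimens needed to call allometry reliably explodes
as the slope x approaches the isometric value 1, and flattens for strongly
allometric slopes.  Two nested models capture this:

* ``hyperbola``          y = m / |x - b|
* ``hyperbola_offset``   y = m / |x - b| + c

where m sets the curve shape, b the position of the vertical asymptote
(expected just off 1) and c a vertical offset absorbing extra y-error.

Fitting minimises the residual sum of squares.  The objective is non-smooth
at b equal to any data abscissa, so the fit profiles b over a grid spanning
the data (solving m, and c, linearly at each candidate b) before a joint
Levenberg-style refinement.  Models are compared with the Gaussian
concentrated-likelihood AIC, n ln(rss/n) + 2k with k = parameters + 1, and
Akaike weights; AIC differences and weights are free of the additive
constant that the concentrated form drops.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special

from .exceptions import FitError, ValidationError

MODELS = ("hyperbola", "hyperbola_offset")

_N_PARAMS = {"hyperbola": 2, "hyperbola_offset": 3}

#: Grid points for the b-profile initialisation.
DEFAULT_GRID_SIZE = 201


@dataclass(frozen=True)
class ScalingPoint:
    """One variable's (slope, minimum sample size) observation.

    ``censored`` marks minimum-n values that never reached the agreement
    level within the sweep (known only as "> sweep max"); censored points
    are excluded from fitting rather than truncated to their bound.
    """

    x: float
    y: float
    censored: bool = False

    def __post_init__(self):
        if not self.censored and self.y < 3:
            raise ValidationError(
                f"minimum sample size must be >= 3, got {self.y}"
            )


def _predict(x, params, model):
    d = np.maximum(np.abs(x - params["b"]), 1e-12)
    y = params["m"] / d
    if model == "hyperbola_offset":
        y = y + params["c"]
    return y


def profile_rss(x, y, b, model):
    """Best (m[, c]) and rss at a fixed asymptote position b (linear solve)."""
    w = 1.0 / np.abs(x - b)
    if model == "hyperbola_offset":
        A = np.column_stack([w, np.ones_like(w)])
    else:
        A = w[:, None]
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    return coef, float(resid @ resid)


def _jacobian(x, params, model):
    d = x - params["b"]
    a = np.maximum(np.abs(d), 1e-12)
    cols = [1.0 / a, params["m"] * np.sign(d) / (a * a)]
    if model == "hyperbola_offset":
        cols.append(np.ones_like(x))
    return np.column_stack(cols)


def fit_hyperbola(points, model: str = "hyperbola",
                  grid_size: int = DEFAULT_GRID_SIZE) -> "HyperbolicFitResults":
    """Least-squares fit of a hyperbolic minimum-n model.

    Censored points are excluded.  Initialisation profiles b over a grid on
    the open interval (min x, max x), skipping candidates that coincide with
    data abscissae; a joint nonlinear refinement follows, and the grid
    optimum is kept if refinement fails to improve it.  Parameter CIs come
    from the asymptotic Jacobian covariance with t quantiles.
    """
    if model not in MODELS:
        raise ValidationError(f"unknown model {model!r}; expected one of {MODELS}")
    used = [p for p in points if not p.censored]
    n_par = _N_PARAMS[model]
    if len(used) < n_par + 2:
        raise FitError(
            f"{model} needs at least {n_par + 2} uncensored points, got {len(used)}"
        )
    x = np.array([p.x for p in used], dtype=float)
    y = np.array([p.y for p in used], dtype=float)
    order = np.argsort(x, kind="stable")
    x, y = x[order], y[order]
    xmin, xmax = float(x.min()), float(x.max())
    if xmin == xmax:
        raise FitError("all points share one abscissa; the asymptote is unidentified")

    candidates = np.linspace(xmin, xmax, grid_size + 2)[1:-1]
    if model == "hyperbola_offset":
        # ensure the nested model never beats the extended one: include the
        # simpler model's optimal b among the candidates
        base = fit_hyperbola(points, "hyperbola", grid_size)
        candidates = np.append(candidates, base.params["b"])
    tol = 1e-9 * (xmax - xmin)
    candidates = candidates[
        np.min(np.abs(candidates[:, None] - x[None, :]), axis=1) > tol
    ]
    if candidates.size == 0:
        raise FitError("no admissible asymptote candidates between the data abscissae")

    best_b, best_coef, best_rss = None, None, np.inf
    for b in candidates:
        coef, rss = profile_rss(x, y, b, model)
        if rss < best_rss:
            best_b, best_coef, best_rss = float(b), coef, rss

    names = ["m", "b"] + (["c"] if model == "hyperbola_offset" else [])
    if model == "hyperbola_offset":
        theta0 = [best_coef[0], best_b, best_coef[1]]
    else:
        theta0 = [best_coef[0], best_b]

    def residual(theta):
        params = dict(zip(names, theta))
        return _predict(x, params, model) - y

    sol = optimize.least_squares(
        residual, theta0, ftol=1e-14, xtol=1e-14, gtol=1e-14, max_nfev=20000
    )
    refined_rss = float(sol.fun @ sol.fun)
    if sol.success and refined_rss <= best_rss:
        theta = sol.x
        rss = refined_rss
    else:
        theta = np.asarray(theta0, dtype=float)
        rss = best_rss
    params = dict(zip(names, (float(t) for t in theta)))

    dof = len(used) - n_par
    J = _jacobian(x, params, model)
    cov = np.linalg.pinv(J.T @ J) * (rss / dof if dof > 0 else np.nan)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    tq = float(special.stdtrit(dof, 0.975)) if dof > 0 else np.nan
    conf_int = {
        name: (params[name] - tq * se[i], params[name] + tq * se[i])
        for i, name in enumerate(names)
    }
    aic = len(used) * float(np.log(max(rss, 1e-300) / len(used))) + 2 * (n_par + 1)
    return HyperbolicFitResults(
        model=model,
        params=params,
        conf_int=conf_int,
        rss=rss,
        n_points=len(used),
        aic=aic,
        _xy=(tuple(x), tuple(y)),
    )


@dataclass
class HyperbolicFitResults:
    """Fitted hyperbolic minimum-n model: estimates, 95% CIs, rss and AIC."""

    model: str
    params: dict
    conf_int: dict
    rss: float
    n_points: int
    aic: float
    _xy: tuple = None

    @property
    def n_params(self) -> int:
        return _N_PARAMS[self.model]

    def predict(self, x) -> np.ndarray:
        return _predict(np.asarray(x, dtype=float), self.params, self.model)

    def summary(self) -> pd.DataFrame:
        rows = [
            {
                "parameter": name,
                "estimate": self.params[name],
                "ci_low": self.conf_int[name][0],
                "ci_high": self.conf_int[name][1],
            }
            for name in self.params
        ]
        return pd.DataFrame(rows)


class MinimumSampleSizeModel:
    """Model object for the minimum-n-vs-slope curve (fit() -> results)."""

    def __init__(self, points, model: str = "hyperbola"):
        self.points = list(points)
        self.model = model

    def fit(self, grid_size: int = DEFAULT_GRID_SIZE) -> HyperbolicFitResults:
        return fit_hyperbola(self.points, self.model, grid_size)


def akaike_weights(delta) -> np.ndarray:
    """Akaike weights exp(-delta/2), normalised to sum to 1."""
    rel = np.exp(-0.5 * np.asarray(delta, dtype=float))
    return rel / rel.sum()


@dataclass
class ModelComparison:
    """Delta-AIC and Akaike weights across fits of one point set."""

    table: pd.DataFrame

    @property
    def weights(self) -> np.ndarray:
        return self.table["weight"].to_numpy()

    @property
    def best(self) -> str:
        return str(self.table.loc[self.table["aic"].idxmin(), "model"])


def compare_models(fits) -> ModelComparison:
    """AIC comparison of hyperbolic fits sharing one point set."""
    fits = list(fits)
    if not fits:
        raise ValidationError("need at least one fit to compare")
    ref = fits[0]._xy
    for f in fits[1:]:
        if f._xy != ref:
            raise ValidationError("fits are not on the same point set")
    aic = np.array([f.aic for f in fits])
    delta = aic - aic.min()
    w = akaike_weights(delta)
    table = pd.DataFrame(
        {
            "model": [f.model for f in fits],
            "k": [f.n_params for f in fits],
            "n_points": [f.n_points for f in fits],
            "rss": [f.rss for f in fits],
            "aic": aic,
            "delta_aic": delta,
            "weight": w,
        }
    )
    return ModelComparison(table)
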