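"""Plots of power curves, error rates and the minimum-n-vs-slope relation.

All plots render from the tabular data products (power/error/min-n tables),
so figures are cosmetic conveniences; nothing downstream depends on them.
"""

from __future__ import annotations

import numpy as np

_CATEGORY_COLORS = {
    "p_positive": "#2ca02c",
    "p_isometric": "#d9d9d9",
    "p_negative": "#d62728",
}


def _get_ax(ax):
    if ax is not None:
        return ax
    import matplotlib.pyplot as plt

    _, ax = plt.subplots()
    return ax


def plot_power_curve(curve, ax=None):
    """Stacked proportions of scaling calls vs subsample size for one variable."""
    ax = _get_ax(ax)
    p = curve.proportions()
    n = p.index.to_numpy()
    ax.stackplot(
        n,
        [p[c].to_numpy() for c in _CATEGORY_COLORS],
        labels=[c[2:] for c in _CATEGORY_COLORS],
        colors=list(_CATEGORY_COLORS.values()),
    )
    ax.set_xlabel("subsample size n")
    ax.set_ylabel("proportion of replicates")
    ax.set_ylim(0, 1)
    ax.set_title(f"{curve.variable_id} ({curve.method}, {curve.scheme})")
    ax.legend(loc="center right", fontsize="small")
    return ax


def plot_error_rates(aggregate, ax=None):
    """Mean error rates with one-SD bands vs subsample size."""
    ax = _get_ax(ax)
    rates = aggregate.rates
    n = rates.index.to_numpy()
    for col, color in (
        ("false_isometry", "#d62728"),
        ("false_allometry", "#2ca02c"),
        ("sign_error", "#1f77b4"),
    ):
        mean = rates[col].to_numpy()
        ax.plot(n, mean, color=color, label=col.replace("_", " "))
        sd_col = f"{col}_sd"
        if sd_col in rates:
            sd = rates[sd_col].to_numpy()
            ax.plot(n, np.clip(mean - sd, 0, 1), color=color, ls=":", lw=0.8)
            ax.plot(n, np.clip(mean + sd, 0, 1), color=color, ls=":", lw=0.8)
    ax.set_xlabel("subsample size n")
    ax.set_ylabel("error rate")
    ax.set_ylim(0, 1)
    ax.legend(fontsize="small")
    return ax


def plot_min_sample_curve(points, fit=None, ax=None):
    """Minimum sample size vs slope, with an optional fitted hyperbola."""
    ax = _get_ax(ax)
    xs = [p.x for p in points if not p.censored]
    ys = [p.y for p in points if not p.censored]
    ax.scatter(xs, ys, color="black", zorder=3, label="variables")
    cx = [p.x for p in points if p.censored]
    cy = [p.y for p in points if p.censored]
    if cx:
        ax.scatter(cx, cy, marker="^", color="grey", zorder=3, label="censored (>)")
    if fit is not None and xs:
        b = fit.params["b"]
        lo, hi = min(xs), max(xs)
        for seg in ((lo, b - 1e-3), (b + 1e-3, hi)):
            grid = np.linspace(*seg, 200)
            ax.plot(grid, fit.predict(grid), color="#1f77b4", lw=1.5)
    ax.axvline(1.0, ls="--", color="grey", lw=0.8)
    ax.set_xlabel("slope")
    ax.set_ylabel("minimum sample size")
    ax.legend(fontsize="small")
    return ax
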