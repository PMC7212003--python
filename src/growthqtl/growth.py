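"""Sigmoid growth modeling of plant-height time series.

The central model is the three-parameter Weibull sigmoid

    f(x) = L * (1 - exp(-(x/x0)^b))

with height f in metres, x the time axis in days after sowing (DAS),
L > 0 the asymptote (terminal height, m), x0 > 0 the inflection-point
parameter (DAS), and b > 0 a unitless shape ("growth rate") constant.
Unlike the logistic, the Weibull inflection is not pinned to L/2, which
suits the asymmetric elongation of maize.

The absolute growth rate (AGR) is the calculus derivative

    f'(x) = L * (b/x0) * (x/x0)^(b-1) * exp(-(x/x0)^b)

whose exact argmax is x0*((b-1)/b)^(1/b) for b > 1.  Field summaries
conventionally quote the maximum AGR at x = x0; both values are exposed.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import optimize, stats

__all__ = [
    "WeibullFit",
    "GrowthSummary",
    "weibull",
    "weibull_derivative",
    "fit_weibull",
    "fit_sigmoid",
    "absolute_growth_rate",
    "max_agr",
    "agr_argmax",
    "select_growth_model",
    "goodness_of_fit_filter",
    "impute_daily_heights",
    "SIGMOID_FAMILIES",
    "DEFAULT_NOISE_SD",
]

#: reference measurement-noise scale (m) for the goodness-of-fit filter;
#: matches the per-flight height noise the trial model assumes
DEFAULT_NOISE_SD = 0.03


@dataclass
class WeibullFit:
    """Fitted Weibull parameters plus diagnostics for one entry."""

    L: float
    x0: float
    b: float
    r2: float
    rmse: float
    df_resid: int
    converged: bool
    gof_pass: bool = True
    family: str = "weibull"

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GrowthSummary:
    """Derived growth quantities: peak AGR and the daily imputed series."""

    max_agr_mm_day: float        # AGR at the exact argmax, mm/day
    max_agr_at_x0_mm_day: float  # AGR evaluated at x = x0 (field convention)
    das_max_agr: float           # exact argmax, DAS
    daily_das: np.ndarray
    daily_height_m: np.ndarray


# ---------------------------------------------------------------------------
# model functions
# ---------------------------------------------------------------------------

def weibull(x, L, x0, b):
    """Weibull sigmoid height (m) at DAS ``x``; vectorised in x."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("DAS must be non-negative")
    out = L * (1.0 - np.exp(-((x / x0) ** b)))
    return float(out) if out.ndim == 0 else out


def weibull_derivative(x, L, x0, b):
    """Analytic df/dx in m/day; defined as 0 at x=0 for b>1."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("DAS must be non-negative")
    with np.errstate(divide="ignore", invalid="ignore"):
        u = x / x0
        out = np.where(
            x == 0,
            0.0 if b > 1 else (L * b / x0 if b == 1 else np.inf),
            L * (b / x0) * u ** (b - 1.0) * np.exp(-(u ** b)),
        )
    return float(out) if out.ndim == 0 else out


def _logistic(x, L, x0, k):
    return L / (1.0 + np.exp(-k * (np.asarray(x, float) - x0)))


def _gompertz(x, L, x0, k):
    return L * np.exp(-np.exp(-k * (np.asarray(x, float) - x0)))


def _probit(x, L, x0, s):
    return L * stats.norm.cdf((np.asarray(x, float) - x0) / s)


def _weibull3(x, L, x0, b):
    return L * (1.0 - np.exp(-((np.asarray(x, float) / x0) ** b)))


# candidate sigmoid families, in fixed tie-break order
SIGMOID_FAMILIES: dict[str, callable] = {
    "weibull": _weibull3,
    "logistic": _logistic,
    "gompertz": _gompertz,
    "probit": _probit,
}


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _r2_rmse(y, yhat):
    resid = y - yhat
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else np.nan
    return r2, float(np.sqrt(rss / y.size)), rss


def _initial_guess(t, y):
    L0 = max(float(np.max(y)), 1e-3)
    above = t[y > 0.5 * L0]
    x00 = float(above[0]) if above.size else float(np.median(t))
    x00 = max(x00, 1.0)
    return L0, x00, 5.0


def fit_weibull(
    times,
    heights,
    init: tuple[float, float, float] | None = None,
    bounds: tuple | None = None,
) -> WeibullFit:
    """Least-squares Weibull fit to one entry's (DAS, height) series.

    Requires at least 4 observations on at least 3 distinct times.
    Degenerate data (constant heights) returns a flagged non-fit rather
    than raising.  Default bounds: L in (0, 3*max(y)], x0 in (0, 200],
    b in (0.5, 30].
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(heights, dtype=float)
    order = np.argsort(t)  # order-invariance
    t, y = t[order], y[order]
    if t.size < 4:
        raise ValueError("need at least 4 (time, height) pairs")
    if np.unique(t).size < 3:
        raise ValueError("need at least 3 distinct times")
    if np.ptp(y) <= 0:
        return WeibullFit(np.nan, np.nan, np.nan, np.nan, np.nan,
                          int(t.size - 3), converged=False, gof_pass=False)
    p0 = init if init is not None else _initial_guess(t, y)
    if bounds is None:
        bounds = ([1e-6, 1e-6, 0.5], [3.0 * max(float(np.max(y)), 1e-3), 200.0, 30.0])
    p0 = np.clip(p0, bounds[0], bounds[1])
    try:
        popt, _ = optimize.curve_fit(
            _weibull3, t, y, p0=p0, bounds=bounds, maxfev=20000
        )
        converged = True
    except RuntimeError:
        popt, converged = p0, False
    r2, rmse, _ = _r2_rmse(y, _weibull3(t, *popt))
    return WeibullFit(float(popt[0]), float(popt[1]), float(popt[2]),
                      r2, rmse, int(t.size - 3), converged=converged)


def fit_sigmoid(family: str, times, heights) -> WeibullFit:
    """Fit one named sigmoid family; same diagnostics container."""
    f = SIGMOID_FAMILIES[family]
    t = np.asarray(times, dtype=float)
    y = np.asarray(heights, dtype=float)
    order = np.argsort(t)
    t, y = t[order], y[order]
    if family == "weibull":
        fit = fit_weibull(t, y)
        fit.family = family
        return fit
    L0 = max(float(np.max(y)), 1e-3)
    above = t[y > 0.5 * L0]
    x00 = float(above[0]) if above.size else float(np.median(t))
    if family == "probit":
        p0, lo, hi = (L0, x00, 10.0), [1e-6, 1e-6, 0.5], [3 * L0, 200.0, 100.0]
    else:
        p0, lo, hi = (L0, x00, 0.1), [1e-6, 1e-6, 1e-3], [3 * L0, 200.0, 5.0]
    try:
        popt, _ = optimize.curve_fit(f, t, y, p0=p0, bounds=(lo, hi), maxfev=20000)
        converged = True
    except RuntimeError:
        popt, converged = np.asarray(p0), False
    r2, rmse, _ = _r2_rmse(y, f(t, *popt))
    return WeibullFit(float(popt[0]), float(popt[1]), float(popt[2]),
                      r2, rmse, int(t.size - 3), converged=converged, family=family)


# ---------------------------------------------------------------------------
# derived quantities
# ---------------------------------------------------------------------------

def absolute_growth_rate(fit: WeibullFit, x) -> float | np.ndarray:
    """AGR in mm/day at DAS ``x`` from a converged fit."""
    if not fit.converged:
        raise ValueError("AGR requires a converged fit")
    return 1000.0 * weibull_derivative(x, fit.L, fit.x0, fit.b)


def agr_argmax(x0: float, b: float) -> float:
    """Exact DAS of maximum AGR: x0*((b-1)/b)^(1/b) for b > 1, else 0."""
    if b <= 1:
        return 0.0
    return x0 * ((b - 1.0) / b) ** (1.0 / b)


def max_agr(fit: WeibullFit) -> tuple[float, float, float]:
    """Return (AGR at exact argmax, AGR at x0, argmax DAS), AGR in mm/day."""
    xm = agr_argmax(fit.x0, fit.b)
    return (
        float(absolute_growth_rate(fit, xm)),
        float(absolute_growth_rate(fit, fit.x0)),
        xm,
    )


# ---------------------------------------------------------------------------
# model selection and filtering
# ---------------------------------------------------------------------------

def _aicc(n, rss, k):
    # Gaussian AICc; k counts curve parameters + residual variance
    if rss <= 0:
        rss = 1e-300
    aic = n * np.log(rss / n) + 2 * k
    denom = n - k - 1
    return aic + (2 * k * (k + 1) / denom if denom > 0 else np.inf)


def select_growth_model(times, heights, candidates=None):
    """Fit each candidate sigmoid and pick the lowest-AICc family.

    Returns ``(best_family, table)`` where *table* maps family name to a
    dict with the fit and its AICc.  Exact ties resolve to the earliest
    family in the fixed order and are flagged in the table.
    """
    names = list(candidates) if candidates is not None else list(SIGMOID_FAMILIES)
    if not names:
        raise ValueError("no candidate families")
    t = np.asarray(times, dtype=float)
    y = np.asarray(heights, dtype=float)
    table = {}
    for name in names:
        fit = fit_sigmoid(name, t, y)
        rss = fit.rmse ** 2 * t.size if np.isfinite(fit.rmse) else np.inf
        aicc = _aicc(t.size, rss, 4) if fit.converged else np.inf
        table[name] = {"fit": fit, "aicc": aicc}
    finite = [n for n in names if np.isfinite(table[n]["aicc"])]
    if not finite:
        raise RuntimeError("no candidate family converged")
    best_val = min(table[n]["aicc"] for n in finite)
    winners = [n for n in finite if table[n]["aicc"] == best_val]
    best = winners[0]
    for n in names:
        table[n]["selected"] = n == best
        table[n]["tied"] = len(winners) > 1 and n in winners
    return best, table


def goodness_of_fit_filter(
    fit: WeibullFit,
    alpha: float = 0.05,
    noise_var: float = DEFAULT_NOISE_SD ** 2,
) -> bool:
    """Chi-square screen for poor fits; True = keep.

    A one-sided likelihood-ratio statistic compares the fit's residual
    variance s2 = RMSE^2 * n/df against a reference measurement-noise
    variance: X2 = df * (s2/v0 - 1 - ln(s2/v0)) when s2 > v0, else 0.
    The fit is dropped when X2 strictly exceeds the chi-square critical
    value at ``alpha`` with df = 1 (3.841 at alpha = 0.05); a statistic
    exactly at the critical value keeps the fit.
    """
    if not fit.converged:
        return False
    if fit.df_resid < 1:
        raise ValueError("goodness-of-fit needs residual df >= 1")
    n = fit.df_resid + 3
    s2 = fit.rmse ** 2 * n / fit.df_resid
    if s2 <= noise_var:
        return True
    ratio = s2 / noise_var
    x2 = fit.df_resid * (ratio - 1.0 - np.log(ratio))
    crit = stats.chi2.ppf(1.0 - alpha, df=1)
    return bool(x2 <= crit)


def impute_daily_heights(fit: WeibullFit, day_range=(1, 85)) -> GrowthSummary:
    """Evaluate the fitted curve on integer DAS over ``day_range``.

    The default window 1..85 DAS yields exactly 85 values, covering
    sowing through terminal height for the study system.
    """
    if not fit.converged:
        raise ValueError("cannot impute from a non-converged fit")
    days = np.arange(int(day_range[0]), int(day_range[1]) + 1)
    heights = weibull(days.astype(float), fit.L, fit.x0, fit.b)
    agr_peak, agr_at_x0, xm = max_agr(fit)
    return GrowthSummary(
        max_agr_mm_day=agr_peak,
        max_agr_at_x0_mm_day=agr_at_x0,
        das_max_agr=xm,
        daily_das=days,
        daily_height_m=np.asarray(heights, dtype=float),
    )
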