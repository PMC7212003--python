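"""REML variance components, BLUPs, heritability, and mean comparisons.

Per flight date (and environment and population) plot heights follow the
randomized-complete-block model with spatial terms

    Y_ijkl = mu + G_i + Rep_j + Range_k + Row_l + eps_ijkl

where every term other than the grand mean is random and independent
Gaussian.  Variance components are estimated by restricted maximum
likelihood: the residual variance is profiled out analytically and the
restricted log-likelihood is maximized over the log variance ratios
gamma_i = sigma_i^2 / sigma_eps^2 with a derivative-free simplex search,
which tolerates boundary (zero-variance) solutions.  Genotype BLUPs are
the usual shrinkage predictors sigma_G^2 Z' V^{-1} (y - mu_hat).

Broad-sense heritability on an entry-mean basis is

    H^2 = sigma_G^2 / (sigma_G^2 + sigma_eps^2 / r)

with r the number of replicates per environment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "ModelSpec",
    "VarianceComponents",
    "fit_reml",
    "fit_reml_by",
    "heritability",
    "percent_variance_table",
    "lsd_test",
]

#: random terms of the plot model, in canonical order, mapped to the
#: observation columns that carry their levels
DEFAULT_TERMS = {"G": "entry", "Rep": "rep", "Range": "range", "Row": "row"}


@dataclass
class ModelSpec:
    response: str = "height_m"
    terms: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_TERMS))


@dataclass
class VarianceComponents:
    sigma2: dict[str, float]       # per term plus "Residual", m^2
    loglik: float                  # restricted log-likelihood at the optimum
    converged: bool
    n_obs: int
    boundary: tuple[str, ...] = () # terms clamped at zero

    @property
    def total(self) -> float:
        return float(sum(self.sigma2.values()))


def _design(levels: pd.Series) -> tuple[np.ndarray, list]:
    cats = pd.Categorical(levels)
    Z = np.zeros((len(levels), len(cats.categories)))
    Z[np.arange(len(levels)), cats.codes] = 1.0
    return Z, list(cats.categories)


def _profiled_negloglik(theta, ZZt, yc, Xc, n, p):
    """-2x restricted log-likelihood with sigma_eps^2 profiled out."""
    H = np.eye(n)
    for g, M in zip(np.exp(np.clip(theta, -30.0, 30.0)), ZZt):
        H += g * M
    try:
        Lc = np.linalg.cholesky(H)
    except np.linalg.LinAlgError:
        return np.inf
    logdetH = 2.0 * np.log(np.diag(Lc)).sum()
    Hy = np.linalg.solve(H, yc)
    HX = np.linalg.solve(H, Xc)
    XtHX = Xc.T @ HX
    sign, logdetXtHX = np.linalg.slogdet(XtHX)
    if sign <= 0:
        return np.inf
    beta = np.linalg.solve(XtHX, Xc.T @ Hy)
    yPy = float(yc @ Hy - (Xc.T @ Hy) @ beta)
    if yPy <= 0:
        return np.inf
    s2 = yPy / (n - p)
    return (n - p) * (np.log(s2) + 1.0) + logdetH + logdetXtHX


def fit_reml(
    observations: pd.DataFrame,
    spec: ModelSpec | None = None,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> tuple[VarianceComponents, pd.DataFrame]:
    """Fit the random-effects plot model by REML.

    Returns ``(varcomp, blups)`` where *blups* has one row per genotype
    with its BLUP deviation and predicted value (grand mean + BLUP).
    Components are clamped at zero (boundary-flagged) rather than allowed
    negative; non-convergence of the simplex search is flagged, never
    silent.
    """
    spec = spec or ModelSpec()
    obs = observations
    terms = {name: col for name, col in spec.terms.items() if col in obs.columns}
    if "G" not in terms:
        raise ValueError("model needs the genotype term")
    y = obs[spec.response].to_numpy(dtype=float)
    n = y.size
    Zs, levels = {}, {}
    for name, col in list(terms.items()):
        Z, lv = _design(obs[col])
        if len(lv) < 2:
            raise ValueError(f"term {name} has fewer than 2 levels")
        Zs[name], levels[name] = Z, lv
    if n <= len(terms) + 1:
        raise ValueError("more model terms than observations")
    names = list(Zs)
    ZZt = [Zs[k] @ Zs[k].T for k in names]
    X = np.ones((n, 1))
    theta0 = np.zeros(len(names))
    res = optimize.minimize(
        _profiled_negloglik, theta0, args=(ZZt, y, X, n, 1),
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": max(tol * 1e-2, 1e-13),
                 "maxiter": max_iter * 50, "maxfev": max_iter * 50,
                 "adaptive": len(names) > 2},
    )
    theta = np.clip(res.x, -30.0, 30.0)
    gamma = np.exp(theta)
    H = np.eye(n)
    for g, M in zip(gamma, ZZt):
        H += g * M
    Hy = np.linalg.solve(H, y)
    HX = np.linalg.solve(H, X)
    XtHX = X.T @ HX
    beta = np.linalg.solve(XtHX, X.T @ Hy)
    resid_rot = np.linalg.solve(H, y - X @ beta)
    s2e = float((y - X @ beta) @ resid_rot / (n - 1))
    if s2e <= 1e-12 * float(np.var(y)) and np.var(y) > 0:
        # residual variance vanishes: the likelihood is maximized on the
        # sigma_eps -> 0 boundary, where shrinkage disappears; report the
        # no-shrinkage (OLS) limit of the components instead of the
        # ill-conditioned ratio decomposition
        Zall = np.column_stack([X] + [Zs[k] for k in names])
        coef, *_ = np.linalg.lstsq(Zall, y, rcond=None)
        rss = float(((y - Zall @ coef) ** 2).sum())
        df_res = n - np.linalg.matrix_rank(Zall)
        s2e = rss / df_res if df_res > 0 else 0.0
        sigma2 = {}
        off = 1
        for name in names:
            q = Zs[name].shape[1]
            eff = coef[off:off + q]
            sigma2[name] = float(np.var(eff - eff.mean(), ddof=1))
            off += q
        gmeans = (Zs["G"].T @ y) / Zs["G"].sum(axis=0)
        mu = float(y.mean())
        blups = pd.DataFrame({
            "entry": levels["G"],
            "blup": gmeans - mu,
            "predicted": gmeans,
        })
        sigma2["Residual"] = s2e
        vc = VarianceComponents(
            sigma2=sigma2,
            loglik=-0.5 * float(res.fun) if np.isfinite(res.fun) else -np.inf,
            converged=bool(res.success),
            n_obs=n,
            boundary=("Residual",),
        )
        return vc, blups
    sigma2 = {name: float(g * s2e) for name, g in zip(names, gamma)}
    # clamp effectively-zero ratios to exact zero and flag the boundary
    boundary = tuple(name for name, th in zip(names, theta) if th <= -29.0)
    for name in boundary:
        sigma2[name] = 0.0
    sigma2["Residual"] = s2e
    vc = VarianceComponents(
        sigma2=sigma2,
        loglik=-0.5 * float(res.fun) if np.isfinite(res.fun) else -np.inf,
        converged=bool(res.success),
        n_obs=n,
        boundary=boundary,
    )
    uG = gamma[names.index("G")] * (Zs["G"].T @ resid_rot)
    mu = float(beta[0])
    blups = pd.DataFrame({
        "entry": levels["G"],
        "blup": uG,
        "predicted": mu + uG,
    })
    return vc, blups


def fit_reml_by(
    observations: pd.DataFrame,
    by=("das", "env"),
    spec: ModelSpec | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit one model per group (per flight date x environment by default).

    Returns long-format variance-component and BLUP tables.
    """
    by = list(by)
    vc_rows, blup_frames = [], []
    for keys, sub in observations.groupby(by, sort=True):
        if not isinstance(keys, tuple):
            keys = (keys,)
        vc, blups = fit_reml(sub, spec=spec)
        shares = percent_variance_table(vc)
        for comp, val in vc.sigma2.items():
            vc_rows.append({
                **dict(zip(by, keys)), "component": comp, "estimate": val,
                "share_pct": shares[comp], "converged": vc.converged,
                "n_obs": vc.n_obs,
            })
        for col, key in zip(by, keys):
            blups[col] = key
        blup_frames.append(blups)
    return pd.DataFrame(vc_rows), pd.concat(blup_frames, ignore_index=True)


def heritability(varcomp: VarianceComponents, n_reps: int) -> float:
    """Entry-mean broad-sense heritability; NaN when G and residual are 0."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    sG = varcomp.sigma2.get("G", 0.0)
    sE = varcomp.sigma2.get("Residual", 0.0)
    if sG < 0 or sE < 0:
        raise ValueError("variance components must be non-negative")
    denom = sG + sE / n_reps
    if denom == 0:
        return float("nan")
    return sG / denom


def percent_variance_table(varcomp: VarianceComponents) -> dict[str, float]:
    """Share of total variance per component, in percent (sums to 100)."""
    total = varcomp.total
    if total <= 0:
        raise ValueError("total variance is zero")
    return {k: 100.0 * v / total for k, v in varcomp.sigma2.items()}


def lsd_test(
    group_means: pd.Series | dict,
    mse: float,
    df: int,
    n_per_group: int,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fisher's least-significant-difference letter grouping.

    Means are sorted descending; any two means differing by more than
    LSD = t(1-alpha/2, df) * sqrt(2*mse/n) receive different letters.
    Letters come from maximal runs of mutually non-different means in
    sorted order (greedy, deterministic).
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    means = pd.Series(group_means).sort_values(ascending=False, kind="mergesort")
    lsd = stats.t.ppf(1.0 - alpha / 2.0, df) * np.sqrt(2.0 * mse / n_per_group)
    m = means.to_numpy()
    k = len(m)
    runs = []
    for i in range(k):
        j = i
        while j + 1 < k and m[i] - m[j + 1] <= lsd:
            j += 1
        if runs and j <= runs[-1][1]:
            continue  # contained in an earlier run
        runs.append((i, j))
    letters = [""] * k
    for li, (i, j) in enumerate(runs):
        ch = chr(ord("a") + li)
        for t_ in range(i, j + 1):
            letters[t_] += ch
    return pd.DataFrame({
        "group": means.index, "mean": m, "letters": letters,
    })
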