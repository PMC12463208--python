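"""Conditional logistic estimation of the cyclone-mortality association.

For matched set s with members i, covariate rows x_i and the observed case
c(s), the conditional log-likelihood is

    l(beta) = sum_s [ eta_{c(s)} - log sum_{i in s} exp(eta_i) ],
    eta_i = x_i' beta,

a softmax over set members in which every set-level effect cancels.  Only
informative sets — those with within-set variation in at least one model
column — contribute; the rest are dropped and counted.  The fit uses Newton
iterations with step-halving on the exact gradient and observed information;
standard errors come from the inverse observed information at the optimum.

The odds ratio and its 95% confidence interval for the exposure term are
exp(beta) and exp(beta -/+ 1.96 se); the 1.96 multiplier is fixed.

Meteorological confounders (window mean temperature, window cumulative
precipitation) enter through natural cubic spline bases with six degrees of
freedom by default; time trends enter as a linear year term plus calendar
month indicators, and maternal age at the reference date enters linearly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

CI_MULTIPLIER = 1.96
MAX_ABS_BETA = 15.0  # |beta| beyond this is treated as separation/divergence


# ---------------------------------------------------------------------------
# spline basis


def natural_cubic_basis(values, df: int = 6, knots=None,
                        boundary_knots=None) -> np.ndarray:
    """Natural (restricted) cubic spline basis with ``df`` columns.

    Interior knots sit at equally spaced quantiles of ``values`` (df - 1
    interior knots); boundary knots at the min and max.  The basis is the
    standard truncated-power natural spline (without intercept): column one
    is x itself and the remaining columns are

        d_k(x) - d_{K-1}(x),   d_k(x) = [(x - k_k)_+^3 - (x - k_K)_+^3] / (k_K - k_k)

    over the knot sequence k_1 < ... < k_K, which is linear beyond the
    boundary knots by construction.
    """
    x = np.asarray(values, dtype=float)
    if df < 3:
        raise ValueError("df must be >= 3 for a natural cubic basis")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    if knots is None:
        probs = np.linspace(0, 1, df + 1)[1:-1]
        knots = np.quantile(x, probs)
    knots = np.asarray(knots, dtype=float)
    if boundary_knots is None:
        boundary_knots = (float(np.min(x)), float(np.max(x)))
    lo, hi = boundary_knots
    allk = np.unique(np.concatenate([[lo], knots, [hi]]))
    if len(allk) < df + 1:
        raise ValueError("degenerate knots (constant or near-constant input)")

    def d(k, xx):
        return (np.maximum(xx - k, 0.0) ** 3 - np.maximum(xx - allk[-1], 0.0) ** 3) \
            / (allk[-1] - k)

    cols = [x]
    dK1 = d(allk[-2], x)
    for k in allk[:-2]:
        cols.append(d(k, x) - dK1)
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# model specification and results


@dataclass(frozen=True)
class ModelSpec:
    """What goes into one conditional-logistic run."""

    exposure_window: str = "lag0"
    spline_df: int = 6
    adjust_temperature: bool = True
    adjust_precipitation: bool = True
    adjust_time: bool = True          # linear year + calendar-month indicators
    adjust_maternal_age: bool = True
    adjust_sex: bool = False
    outcome: str = "u5"               # "u5", "infant", or a 0/1 column name

    def __post_init__(self):
        if self.spline_df < 3:
            raise ValueError("spline_df must be >= 3")
        if self.exposure_window not in ("lag0", "lag1", "lag2", "lag02"):
            raise ValueError(f"unknown exposure window {self.exposure_window!r}")


@dataclass
class FitResult:
    """Exposure-term estimate from one conditional-logistic run."""

    beta: float
    se: float
    or_: float
    ci_low: float
    ci_high: float
    p_value: float
    n_sets: int
    n_sets_informative: int
    converged: bool
    n_iter: int
    loglik: float
    columns: list[str] = field(default_factory=list)
    label: str = ""

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "label", "beta", "se", "or_", "ci_low", "ci_high", "p_value",
            "n_sets", "n_sets_informative", "converged", "n_iter", "loglik",
            "columns")}


def or_ci(beta: float, se: float) -> tuple[float, float, float]:
    """Odds ratio and 95% CI from a log-odds estimate and its SE."""
    if se < 0:
        raise ValueError("se must be non-negative")
    with np.errstate(over="ignore"):
        return (float(np.exp(beta)),
                float(np.exp(beta - CI_MULTIPLIER * se)),
                float(np.exp(beta + CI_MULTIPLIER * se)))


# ---------------------------------------------------------------------------
# likelihood core


def _group_index(groups: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sort order and group start offsets for contiguous group reduction."""
    order = np.argsort(groups, kind="mergesort")
    g = groups[order]
    starts = np.flatnonzero(np.r_[True, g[1:] != g[:-1]])
    return order, starts

def clogit_loglik(beta: np.ndarray, X: np.ndarray, y: np.ndarray,
                  groups: np.ndarray) -> float:
    """Conditional log-likelihood at beta (softmax over each matched set)."""
    order, starts = _group_index(np.asarray(groups))
    Xs, ys = X[order], y[order]
    eta = Xs @ beta
    gmax = np.maximum.reduceat(eta, starts)
    sizes = np.diff(np.r_[starts, len(eta)])
    lse = gmax + np.log(np.add.reduceat(np.exp(eta - np.repeat(gmax, sizes)), starts))
    return float(eta[ys == 1].sum() - lse.sum())


def _clogit_newton(X: np.ndarray, y: np.ndarray, groups: np.ndarray,
                   tol: float = 1e-8, max_iter: int = 100):
    """Newton maximization with step-halving; returns beta, cov, info."""
    order, starts = _group_index(np.asarray(groups))
    Xs, ys = X[order], np.asarray(y)[order]
    n, k = Xs.shape
    sizes = np.diff(np.r_[starts, n])
    rep = np.repeat(np.arange(len(starts)), sizes)
    beta = np.zeros(k)

    def ll_grad_hess(b):
        eta = Xs @ b
        gmax = np.maximum.reduceat(eta, starts)
        ex = np.exp(eta - gmax[rep])
        denom = np.add.reduceat(ex, starts)
        p = ex / denom[rep]
        ll = float(eta[ys == 1].sum() - (gmax + np.log(denom)).sum())
        xbar = np.zeros((len(starts), k))
        np.add.at(xbar, rep, p[:, None] * Xs)
        grad = Xs[ys == 1].sum(axis=0) - xbar.sum(axis=0)
        hess = (Xs * p[:, None]).T @ Xs - xbar.T @ xbar  # observed information
        return ll, grad, hess

    ll, grad, hess = ll_grad_hess(beta)
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        if np.linalg.norm(grad, ord=np.inf) <= tol:
            converged = True
            break
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.pinv(hess) @ grad
        norm = np.linalg.norm(step)
        if norm > 20.0:  # trust region against flat-direction runaway
            step *= 20.0 / norm
        new_beta, new = beta + step, None
        for _ in range(30):  # step-halving
            new = ll_grad_hess(new_beta)
            if new[0] >= ll - 1e-12:
                break
            new_beta = beta + (new_beta - beta) / 2.0
        beta, (ll, grad, hess) = new_beta, new
    converged = bool(np.linalg.norm(grad, ord=np.inf) <= tol)
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(hess)
    return beta, cov, ll, n_iter, converged


def clogit(X, y, groups, tol: float = 1e-8, max_iter: int = 100):
    """Low-level conditional-logistic MLE for an arbitrary design matrix.

    Returns (beta, cov, loglik, n_iter, converged).  Rows are set members,
    ``y`` marks the case, ``groups`` the set id.  No informativeness
    filtering or centering is applied here.
    """
    return _clogit_newton(np.asarray(X, float), np.asarray(y, int),
                          np.asarray(groups), tol=tol, max_iter=max_iter)


# ---------------------------------------------------------------------------
# design construction


def build_design(analysis: pd.DataFrame, spec: ModelSpec
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Assemble (X, y, set ids, column names) for one model run.

    The analysis frame is long (one row per set member) with exposure flags
    ``exposed_<window>``, window weather aggregates ``temp_<window>`` /
    ``precip_<window>``, ``reference_date``, and optional ``maternal_age``
    and ``sex``.  Spline knots are placed on the pooled analysis sample.
    The exposure term is always column 0.
    """
    df = analysis
    if spec.outcome == "infant":
        infant_sets = df.loc[(df["role"] == "case")
                             & (df["case_death_age"] < 12), "set_id"]
        df = df[df["set_id"].isin(set(infant_sets))]
    elif spec.outcome != "u5" and spec.outcome in df.columns:
        pass  # generic binary outcome: caller filtered/encoded already

    w = spec.exposure_window
    cols = [df[f"exposed_{w}"].to_numpy(dtype=float)]
    names = [f"exposed_{w}"]
    if spec.adjust_temperature:
        basis = natural_cubic_basis(df[f"temp_{w}"].to_numpy(), df=spec.spline_df)
        cols.extend(basis.T)
        names.extend(f"ns(temp_{w}){j + 1}" for j in range(basis.shape[1]))
    if spec.adjust_precipitation:
        basis = natural_cubic_basis(df[f"precip_{w}"].to_numpy(), df=spec.spline_df)
        cols.extend(basis.T)
        names.extend(f"ns(precip_{w}){j + 1}" for j in range(basis.shape[1]))
    if spec.adjust_time:
        ref = pd.to_datetime(df["reference_date"])
        cols.append(ref.dt.year.to_numpy(dtype=float))
        names.append("year")
        month = ref.dt.month.to_numpy()
        for m in range(2, 13):
            cols.append((month == m).astype(float))
            names.append(f"month_{m}")
    if spec.adjust_maternal_age and "maternal_age" in df:
        cols.append(df["maternal_age"].to_numpy(dtype=float))
        names.append("maternal_age")
    if spec.adjust_sex and "sex" in df:
        cols.append((df["sex"].astype(str) == "female").to_numpy(dtype=float))
        names.append("sex_female")

    X = np.column_stack(cols)
    y = (df["role"] == "case").to_numpy(dtype=int)
    groups = df["set_id"].to_numpy()
    return X, y, groups, names


def _independent_columns(X: np.ndarray, tol: float = 1e-7) -> np.ndarray:
    """Greedy left-to-right selection of numerically independent columns.

    Column 0 (the exposure term) is considered first, so it is always kept
    when it has any variation; later columns that lie in the span of the
    kept ones (within ``tol`` relative residual) are flagged out.
    """
    n, k = X.shape
    keep = np.zeros(k, dtype=bool)
    Q: list[np.ndarray] = []
    for j in range(k):
        v = X[:, j].astype(float)
        norm0 = np.linalg.norm(v)
        if norm0 == 0:
            continue
        for q in Q:
            v = v - (q @ v) * q
        if np.linalg.norm(v) > tol * norm0:
            Q.append(v / np.linalg.norm(v))
            keep[j] = True
    return keep


def _informative_mask(X: np.ndarray, groups: np.ndarray) -> np.ndarray:
    """Rows belonging to sets with within-set variation in some column."""
    order, starts = _group_index(groups)
    Xs = X[order]
    sizes = np.diff(np.r_[starts, len(Xs)])
    rep = np.repeat(np.arange(len(starts)), sizes)
    first = Xs[starts][rep]
    varies = np.add.reduceat((Xs != first).any(axis=1).astype(int), starts) > 0
    keep_sets = np.zeros(len(Xs), dtype=bool)
    keep_sets[order] = varies[rep]
    return keep_sets


def clogit_fit(analysis: pd.DataFrame, spec: ModelSpec | None = None,
               label: str = "") -> FitResult:
    """Fit the conditional logistic model and report the exposure term.

    Uninformative sets (identical design rows for every member) are dropped
    and counted.  Within-set centering of the covariates is applied for
    numerical stability; it leaves the conditional likelihood unchanged.
    Raises ValueError when no informative set remains.
    """
    spec = spec or ModelSpec()
    X, y, groups, names = build_design(analysis, spec)
    n_sets = len(pd.unique(groups))
    keep = _informative_mask(X, groups)
    X, y, groups = X[keep], y[keep], groups[keep]
    n_inf = len(pd.unique(groups))
    if n_inf == 0:
        raise ValueError("no informative matched sets (no within-set variation)")

    # center within sets: absorbs set-level location, improves conditioning
    Xc = X - pd.DataFrame(X).groupby(groups).transform("mean").to_numpy()
    active = np.abs(Xc).max(axis=0) > 1e-12  # inestimable columns drop out
    if not active[0]:
        raise ValueError("no within-set variation in the exposure term")
    Xa = Xc[:, active]
    scale = Xa.std(axis=0)
    Xa = Xa / scale
    indep = _independent_columns(Xa)
    if not indep[0]:
        raise ValueError("no within-set variation in the exposure term")
    active[active] = indep
    Xa, scale = Xa[:, indep], scale[indep]
    beta_s, cov_s, ll, n_iter, converged = _clogit_newton(Xa, y, groups)
    beta = np.zeros(X.shape[1])
    beta[active] = beta_s / scale
    cov00 = cov_s[0, 0] / scale[0] ** 2

    b, se = float(beta[0]), float(np.sqrt(cov00))
    if abs(b) > MAX_ABS_BETA:  # separation: exposure effect diverges
        converged = False
    orr, lo, hi = or_ci(b, se)
    p = float(2.0 * stats.norm.sf(abs(b) / se)) if se > 0 else float("nan")
    return FitResult(beta=b, se=se, or_=orr, ci_low=lo, ci_high=hi, p_value=p,
                     n_sets=n_sets, n_sets_informative=n_inf,
                     converged=bool(converged), n_iter=n_iter, loglik=ll,
                     columns=names, label=label or spec.exposure_window)


# ---------------------------------------------------------------------------
# subgroup comparison, stratified and sensitivity analyses


def subgroup_z(fit1: FitResult, fit2: FitResult) -> tuple[float, float]:
    """Two-sample Z-test comparing exposure coefficients of two strata:
    Z = (beta1 - beta2) / sqrt(SE1^2 + SE2^2), two-sided normal p."""
    denom = float(np.hypot(fit1.se, fit2.se))
    if denom == 0:
        raise ZeroDivisionError("both standard errors are zero")
    z = (fit1.beta - fit2.beta) / denom
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


def stratified_analysis(analysis: pd.DataFrame, stratifier: str,
                        spec: ModelSpec | None = None
                        ) -> tuple[dict[str, FitResult], pd.DataFrame]:
    """Refit the model within each level of a set-level stratifier.

    The stratifier is taken from the case row of each set (household-level
    covariates are shared; child-level ones follow the case).  Returns
    per-level FitResults (levels whose fit fails are omitted) and a table of
    all pairwise Z-test comparisons.
    """
    spec = spec or ModelSpec()
    case_level = analysis[analysis["role"] == "case"][["set_id", stratifier]]
    level_of_set = dict(zip(case_level["set_id"], case_level[stratifier]))
    lv = analysis["set_id"].map(level_of_set)
    fits: dict[str, FitResult] = {}
    for level in sorted(pd.unique(lv.dropna()), key=str):
        sub = analysis[lv == level]
        try:
            fits[str(level)] = clogit_fit(sub, spec, label=f"{stratifier}={level}")
        except ValueError:
            continue
    rows = []
    for (a, fa), (b, fb) in itertools.combinations(fits.items(), 2):
        z, p = subgroup_z(fa, fb)
        rows.append({"level_1": a, "level_2": b, "z": z, "p_value": p})
    return fits, pd.DataFrame(rows, columns=["level_1", "level_2", "z", "p_value"])


def sensitivity_suite(analysis: pd.DataFrame, spec: ModelSpec | None = None,
                      group_col: str = "country") -> dict[str, FitResult | str]:
    """Standard robustness reruns around a base specification.

    (a) spline df 6 -> 3; (b) add child sex; (c) drop time trends;
    (d) leave-one-out over ``group_col`` levels.  Failures are recorded as
    strings and do not stop the suite.
    """
    spec = spec or ModelSpec()
    out: dict[str, FitResult | str] = {}
    variants = [
        ("base", spec),
        ("spline_df_3", replace(spec, spline_df=3)),
        ("add_sex", replace(spec, adjust_sex=True)),
        ("no_time_trend", replace(spec, adjust_time=False)),
    ]
    for name, vspec in variants:
        try:
            out[name] = clogit_fit(analysis, vspec, label=name)
        except Exception as exc:  # propagate per-variant, keep going
            out[name] = f"error: {exc}"
    if group_col in analysis.columns:
        for g in sorted(pd.unique(analysis[group_col].dropna()), key=str):
            name = f"drop_{g}"
            try:
                out[name] = clogit_fit(analysis[analysis[group_col] != g],
                                       spec, label=name)
            except Exception as exc:
                out[name] = f"error: {exc}"
    return out
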