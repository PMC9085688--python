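"""Transformations and linear mixed models with MLPE pair correlation.

Node-level responses (per-population diversity) are modelled with a
landscape-window random intercept.  Link-level responses (pairwise
differentiation) additionally carry a maximum-likelihood population-effects
(MLPE) structure: each pair observation loads on the two populations it
connects, inducing correlation between pairs sharing a population.

The marginal covariance is

    Sigma = s2_w Zw Zw' + s2_p A A' + s2_e I

with Zw the window-indicator matrix and A the n x P pair-incidence matrix
with two unit entries per row (absent at node level).  Variance ratios are
profiled out on the log scale and optimized by analytic-gradient L-BFGS-B
from three fixed starts plus boundary candidates; beta is the GLS solution
at the optimum.  ML is used for model selection, REML for final refits.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "TransformSpec",
    "ModelDesign",
    "FittedLMM",
    "box_cox",
    "standardize",
    "transform_pipeline",
    "build_design_matrix",
    "fit_mixed",
    "aicc",
    "lrt",
    "marginal_r2",
]

_LOG2PI = math.log(2.0 * math.pi)


# ---------------------------------------------------------------------------
# transforms

@dataclass
class TransformSpec:
    """Box-Cox + standardization parameters for one variable."""

    lam: float
    shift: float
    centre: float
    scale: float

    def apply(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float) + self.shift
        if abs(self.lam) < 1e-12:
            y = np.log(x)
        else:
            y = (np.power(x, self.lam) - 1.0) / self.lam
        return (y - self.centre) / self.scale

    def invert(self, y: np.ndarray) -> np.ndarray:
        y = np.asarray(y, dtype=float) * self.scale + self.centre
        if abs(self.lam) < 1e-12:
            x = np.exp(y)
        else:
            x = np.power(y * self.lam + 1.0, 1.0 / self.lam)
        return x - self.shift


def box_cox(
    x: np.ndarray, lam: float | None = None, bounds: tuple = (-3.0, 3.0)
) -> tuple[TransformSpec, np.ndarray]:
    """Box-Cox transform with automatic shift for non-positive data.

    The exponent maximizes the profile log-likelihood over `bounds` unless
    given explicitly.  Non-positive inputs are shifted by |min| + 1% of the
    range first.  The result is centred and scaled to unit SD.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0:
        raise ValueError("cannot transform a constant vector")
    shift = 0.0
    if x.min() <= 0:
        shift = abs(x.min()) + 0.01 * np.ptp(x)
    xs = x + shift
    if lam is None:
        res = optimize.minimize_scalar(
            lambda l: -stats.boxcox_llf(l, xs),
            bounds=bounds,
            method="bounded",
            options={"xatol": 1e-6},
        )
        lam = float(res.x)
    if abs(lam) < 1e-12:
        y = np.log(xs)
    else:
        y = (np.power(xs, lam) - 1.0) / lam
    centre = float(np.mean(y))
    scale = float(np.std(y, ddof=0))
    if scale == 0:
        raise ValueError("transformed vector is constant")
    spec = TransformSpec(lam, shift, centre, scale)
    return spec, (y - centre) / scale


def standardize(x: np.ndarray) -> tuple[TransformSpec, np.ndarray]:
    """Centre and scale only (lambda fixed at 1)."""
    x = np.asarray(x, dtype=float)
    centre, scale = float(np.mean(x)), float(np.std(x, ddof=0))
    if scale == 0:
        raise ValueError("cannot standardize a constant vector")
    # lam=1 Box-Cox is x - 1, so centre on mean(x) - 1
    spec = TransformSpec(1.0, 0.0, centre - 1.0, scale)
    return spec, (x - centre) / scale


def transform_pipeline(df: pd.DataFrame, columns: Sequence[str]) -> tuple[pd.DataFrame, dict]:
    """Box-Cox + standardize each named column; returns new frame + specs."""
    out = df.copy()
    specs = {}
    for col in columns:
        spec, y = box_cox(df[col].to_numpy())
        out[col] = y
        specs[col] = spec
    return out, specs


# ---------------------------------------------------------------------------
# design

@dataclass
class ModelDesign:
    """Fixed-effect layout plus grouping for a mixed model.

    `fixed` lists column names of the data frame entering as predictors
    (already transformed/standardized); quadratic terms are encoded as
    "I(col^2)" and interactions as "a*b".  `basic` names the mandatory
    determinants (population size + isolation at node level, geographic
    distance at link level) that are always included.  `pair_cols`
    identifies the two population-label columns for MLPE structure, or
    None at node level.
    """

    response: str
    fixed: tuple
    basic: tuple
    group_col: str = "window"
    pair_cols: tuple | None = None

    def __post_init__(self) -> None:
        self.fixed = tuple(self.fixed)
        self.basic = tuple(self.basic)
        terms = set(self.basic) | set(self.fixed)
        for t in terms:
            if t.startswith("I(") and t.endswith("^2)"):
                base = t[2:-3]
                if base not in terms:
                    raise ValueError(f"quadratic {t} requires main effect {base}")
            if "*" in t and not t.startswith("I("):
                a, b = t.split("*", 1)
                if a not in terms or b not in terms:
                    raise ValueError(f"interaction {t} requires both mains")

    @property
    def all_terms(self) -> tuple:
        return tuple(self.basic) + tuple(t for t in self.fixed if t not in self.basic)


def _term_column(df: pd.DataFrame, term: str) -> np.ndarray:
    if term.startswith("I(") and term.endswith("^2)"):
        return df[term[2:-3]].to_numpy(dtype=float) ** 2
    if "*" in term:
        a, b = term.split("*", 1)
        return _term_column(df, a) * _term_column(df, b)
    return df[term].to_numpy(dtype=float)


def build_design_matrix(df: pd.DataFrame, design: ModelDesign) -> tuple[np.ndarray, list]:
    """Intercept + one column per term, in design order."""
    terms = design.all_terms
    cols = [np.ones(len(df))] + [_term_column(df, t) for t in terms]
    X = np.column_stack(cols)
    return X, ["(Intercept)", *terms]


def _indicator(labels: Sequence) -> np.ndarray:
    labels = pd.Series(list(labels))
    cats = pd.Categorical(labels)
    Z = np.zeros((len(labels), len(cats.categories)))
    Z[np.arange(len(labels)), cats.codes] = 1.0
    return Z


def pair_incidence(df: pd.DataFrame, pair_cols: tuple) -> np.ndarray:
    """n x P matrix with two unit entries per row (MLPE structure)."""
    a, b = pair_cols
    pops = sorted(set(df[a]) | set(df[b]))
    idx = {p: i for i, p in enumerate(pops)}
    A = np.zeros((len(df), len(pops)))
    for r, (pa, pb) in enumerate(zip(df[a], df[b])):
        A[r, idx[pa]] = 1.0
        A[r, idx[pb]] = 1.0
    return A


# ---------------------------------------------------------------------------
# fitting

@dataclass
class FittedLMM:
    """A converged mixed-model fit."""

    design: ModelDesign
    beta: np.ndarray
    beta_se: np.ndarray
    term_names: list
    sigma2_window: float
    sigma2_pop: float
    sigma2_resid: float
    loglik: float
    n: int
    k: int
    method: str
    X: np.ndarray = field(repr=False)
    converged: bool = True

    @property
    def aicc(self) -> float:
        return aicc(self)

    def coef(self) -> pd.Series:
        return pd.Series(self.beta, index=self.term_names)

    def summary(self) -> dict:
        return {
            "terms": self.term_names,
            "beta": [float(b) for b in self.beta],
            "se": [float(s) for s in self.beta_se],
            "sigma2_window": self.sigma2_window,
            "sigma2_pop": self.sigma2_pop,
            "sigma2_resid": self.sigma2_resid,
            "loglik": self.loglik,
            "n": self.n,
            "k": self.k,
            "method": self.method,
            "AICc": self.aicc,
        }


def _profiled_loglik(
    log_gammas: np.ndarray,
    y: np.ndarray,
    X: np.ndarray,
    parts: list,
    reml: bool,
) -> tuple[float, np.ndarray, float, np.ndarray]:
    """Log-likelihood with the residual variance profiled out.

    V = I + sum_j gamma_j G_j with G_j = Z_j Z_j'.  Returns (loglik, beta,
    sigma2_e, XtViX_inv) at the profiled optimum for these ratios.
    """
    n, p = X.shape
    V = np.eye(n)
    for lg, G in zip(log_gammas, parts):
        V += math.exp(lg) * G
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        return -np.inf, np.zeros(p), 1.0, np.eye(p)
    logdet_v = 2.0 * np.sum(np.log(np.diag(L)))
    Xi = np.linalg.solve(L, X)  # L^-1 X
    yi = np.linalg.solve(L, y)
    XtViX = Xi.T @ Xi
    XtViy = Xi.T @ yi
    try:
        XtViX_inv = np.linalg.inv(XtViX)
    except np.linalg.LinAlgError:
        return -np.inf, np.zeros(p), 1.0, np.eye(p)
    beta = XtViX_inv @ XtViy
    r = yi - Xi @ beta
    rss = float(r @ r)
    if reml:
        dof = n - p
        sigma2 = rss / dof
        sign, logdet_x = np.linalg.slogdet(XtViX)
        ll = -0.5 * (
            dof * _LOG2PI + dof * math.log(sigma2) + dof + logdet_v + logdet_x
        )
    else:
        sigma2 = rss / n
        ll = -0.5 * (n * _LOG2PI + n * math.log(sigma2) + n + logdet_v)
    return ll, beta, sigma2, XtViX_inv


def _loglik_and_grad(
    log_gammas: np.ndarray,
    y: np.ndarray,
    X: np.ndarray,
    parts: list,
    reml: bool,
) -> tuple[float, np.ndarray]:
    """Profiled log-likelihood and its gradient w.r.t. the log variance
    ratios (envelope theorem: beta and sigma2 are at their conditional
    optima, so only the explicit V dependence contributes)."""
    n, p = X.shape
    gammas = np.exp(np.clip(log_gammas, -60.0, 60.0))
    V = np.eye(n)
    for g, G in zip(gammas, parts):
        V += g * G
    try:
        L = np.linalg.cholesky(V)
        logdet_v = 2.0 * np.sum(np.log(np.diag(L)))
        Vi = np.linalg.inv(V)
        XtViX = X.T @ Vi @ X
        # unbounded variance ratios drive X'V^-1 X singular (e.g. the
        # intercept lies in the window-indicator span): reject that region
        if np.linalg.cond(XtViX) > 1e10:
            return -1e12, np.zeros_like(log_gammas)
        XtViX_inv = np.linalg.inv(XtViX)
    except np.linalg.LinAlgError:
        return -1e12, np.zeros_like(log_gammas)
    beta = XtViX_inv @ (X.T @ (Vi @ y))
    r = y - X @ beta
    u = Vi @ r
    rss = float(r @ u)
    if not math.isfinite(rss) or rss <= 0:
        return -1e12, np.zeros_like(log_gammas)
    if reml:
        dof = n - p
        sigma2 = rss / dof
        sign, logdet_x = np.linalg.slogdet(XtViX)
        ll = -0.5 * (dof * _LOG2PI + dof * math.log(sigma2) + dof + logdet_v + logdet_x)
        P = Vi - Vi @ X @ XtViX_inv @ X.T @ Vi
        trace_mat = P
    else:
        sigma2 = rss / n
        ll = -0.5 * (n * _LOG2PI + n * math.log(sigma2) + n + logdet_v)
        trace_mat = Vi
    grad = np.empty_like(log_gammas, dtype=float)
    for j, G in enumerate(parts):
        tr = float(np.sum(trace_mat * G.T))
        quad = float(u @ (G @ u))
        grad[j] = -0.5 * (tr - quad / sigma2) * gammas[j]
    return ll, grad


_STARTS_1 = [np.array([-2.0]), np.array([0.0]), np.array([2.0])]
_STARTS_2 = [np.array([-2.0, -2.0]), np.array([0.0, 0.0]), np.array([2.0, 0.0])]


def fit_mixed(
    design: ModelDesign,
    data: pd.DataFrame,
    method: str = "ML",
    force_zero_variances: bool = False,
) -> FittedLMM:
    """Fit the window-intercept (node) or window+MLPE (link) mixed model.

    Variance ratios gamma = sigma2_component / sigma2_resid are optimized
    on the log scale by Nelder-Mead from three fixed starts (deterministic
    given data); a boundary-at-zero candidate for each component is also
    evaluated.  ``force_zero_variances`` pins all random variances at 0
    (OLS), used in oracle tests.
    """
    if method not in ("ML", "REML"):
        raise ValueError("method must be ML or REML")
    reml = method == "REML"
    y = data[design.response].to_numpy(dtype=float)
    X, term_names = build_design_matrix(data, design)
    n, p = X.shape
    Zw = _indicator(data[design.group_col])
    parts = [Zw @ Zw.T]
    has_pair = design.pair_cols is not None
    if has_pair:
        A = pair_incidence(data, design.pair_cols)
        parts.append(A @ A.T)
    n_var = 1 + len(parts)  # residual + components
    k = p + n_var
    if n <= k + 1:
        raise ValueError(f"n = {n} too small for k = {k} parameters")

    if force_zero_variances:
        ll, beta, sigma2, XtViX_inv = _profiled_loglik(
            np.full(len(parts), -np.inf), y, X, [np.zeros((n, n))] * len(parts), reml
        )
        se = np.sqrt(np.maximum(np.diag(XtViX_inv) * sigma2, 0.0))
        return FittedLMM(
            design, beta, se, term_names, 0.0, 0.0, sigma2, ll, n, k, method, X
        )

    starts = _STARTS_1 if len(parts) == 1 else _STARTS_2
    NEG_INF_LOG = -30.0  # gamma ~ 1e-13: numerically zero component
    bounds = [(NEG_INF_LOG, 16.0)] * len(parts)

    def value_grad(lg: np.ndarray) -> tuple[float, np.ndarray]:
        ll, g = _loglik_and_grad(lg, y, X, parts, reml)
        return -ll, -g

    candidates = []
    for s0 in starts:
        res = optimize.minimize(
            value_grad,
            s0,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": 1e-12, "gtol": 1e-9, "maxiter": 500},
        )
        candidates.append((res.fun, np.clip(res.x, NEG_INF_LOG, 16.0), res.success))
    # boundary candidates: each subset of components pinned at zero
    for mask in itertools.product([False, True], repeat=len(parts)):
        if not any(mask):
            continue
        free = [i for i, m in enumerate(mask) if not m]
        full0 = np.full(len(parts), NEG_INF_LOG)
        if free:

            def vg_sub(lg_free, free=free):
                full = np.full(len(parts), NEG_INF_LOG)
                full[free] = lg_free
                f, g = value_grad(full)
                return f, g[free]

            res = optimize.minimize(
                vg_sub,
                np.zeros(len(free)),
                jac=True,
                method="L-BFGS-B",
                bounds=[bounds[i] for i in free],
                options={"ftol": 1e-12, "gtol": 1e-9, "maxiter": 500},
            )
            full0[free] = np.clip(res.x, NEG_INF_LOG, 16.0)
            candidates.append((res.fun, full0, res.success))
        else:
            candidates.append((value_grad(full0)[0], full0, True))

    candidates.sort(key=lambda c: c[0])
    fun, lg_best, success = candidates[0]
    if not math.isfinite(fun):
        raise RuntimeError("mixed-model fit failed to converge from all starts")
    ll, beta, sigma2, XtViX_inv = _profiled_loglik(lg_best, y, X, parts, reml)
    gammas = np.exp(lg_best)
    gammas[lg_best <= NEG_INF_LOG + 1e-9] = 0.0
    s2_window = float(gammas[0] * sigma2)
    s2_pop = float(gammas[1] * sigma2) if has_pair else 0.0
    se = np.sqrt(np.maximum(np.diag(XtViX_inv) * sigma2, 0.0))
    return FittedLMM(
        design,
        beta,
        se,
        term_names,
        s2_window,
        s2_pop,
        float(sigma2),
        float(ll),
        n,
        k,
        method,
        X,
        converged=bool(success),
    )


# ---------------------------------------------------------------------------
# inference

def aicc(fit: FittedLMM) -> float:
    """Small-sample corrected Akaike information criterion."""
    n, k = fit.n, fit.k
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n = {n}, k = {k}")
    return -2.0 * fit.loglik + 2.0 * k + 2.0 * k * (k + 1.0) / (n - k - 1.0)


def lrt(full: FittedLMM, reduced: FittedLMM) -> tuple[float, int, float]:
    """Likelihood-ratio test of nested fixed structures (ML fits only)."""
    if full.method != "ML" or reduced.method != "ML":
        raise ValueError("likelihood-ratio tests require ML fits")
    full_terms = set(full.term_names)
    red_terms = set(reduced.term_names)
    if not red_terms <= full_terms:
        raise ValueError("reduced model terms are not a subset of the full model")
    stat = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    df = len(full_terms) - len(red_terms)
    if df == 0:
        return stat, 0, 1.0
    p = float(stats.chi2.sf(stat, df))
    return stat, df, p


def marginal_r2(fit: FittedLMM) -> float:
    """Nakagawa-Schielzeth marginal R^2.

    var(X beta) / (var(X beta) + s2_w + s2_p * 2 + s2_e); the MLPE
    component enters with weight 2 because every pair row loads on two
    population effects.
    """
    fitted = fit.X @ fit.beta
    var_f = float(np.var(fitted, ddof=0))
    m_bar = 2.0 if fit.design.pair_cols is not None else 0.0
    total = var_f + fit.sigma2_window + fit.sigma2_pop * m_bar + fit.sigma2_resid
    if total == 0:
        raise ValueError("zero total variance")
    return var_f / total
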