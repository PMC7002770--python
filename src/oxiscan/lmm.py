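"""Gaussian linear mixed models with a single random intercept.

The model is ``y = X b + u[group] + e`` with ``u ~ N(0, s2_group)`` and
``e ~ N(0, s2_resid)``. Fitting profiles the likelihood down to the single
variance ratio ``theta = s2_group / s2_resid``: for fixed theta the GLS
estimate of ``b`` and the residual variance have closed forms, so the
optimisation is a deterministic one-dimensional search (coarse log-scale
grid, then bounded refinement; the boundary theta = 0 is always evaluated
and allowed). Both ML and REML criteria are supported; likelihood-ratio
comparisons require ML.

Per-group algebra: with J the all-ones matrix and n_g the group size,
``(I + theta J)^-1 = I - theta/(1 + theta n_g) J`` and
``log|I + theta J| = log(1 + theta n_g)``, so every objective evaluation
costs O(n_groups * p^2) after one pass of precomputed cross-products.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, replace
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import (
    CohortSizeError,
    DegenerateDataError,
    FitError,
    NestingError,
    RankError,
    ValidationError,
)

log = logging.getLogger(__name__)

_BOUNDARY_TOL = 1e-8


@dataclass(frozen=True)
class ModelSpec:
    """Fixed-effect structure plus the random-intercept grouping factor.

    ``terms`` are column names entering the fixed part (an intercept is
    always included); ``interactions`` are pairs whose elementwise product
    is added as an extra column named ``"a:b"``.
    """

    response: str
    terms: tuple[str, ...]
    group: str
    interactions: tuple[tuple[str, str], ...] = ()

    def drop_terms(self, *names: str) -> "ModelSpec":
        """Nested spec with the given fixed-effect terms removed."""
        missing = [t for t in names if t not in self.terms]
        if missing:
            raise ValidationError(f"cannot drop absent terms: {missing}")
        return replace(self, terms=tuple(t for t in self.terms
                                         if t not in names))

    def drop_interactions(self) -> "ModelSpec":
        return replace(self, interactions=())

    @property
    def columns(self) -> tuple[str, ...]:
        cols = [self.response, *self.terms, self.group]
        for a, b in self.interactions:
            for c in (a, b):
                if c not in cols:
                    cols.append(c)
        return tuple(cols)


class R2Pair(NamedTuple):
    marginal: float
    conditional: float


@dataclass
class LmmFit:
    """Fitted state of a single-random-intercept Gaussian mixed model."""

    spec: ModelSpec
    method: str                      # "ML" or "REML"
    params: pd.Series                # fixed-effect estimates
    bse: pd.Series                   # Wald standard errors
    sigma2_group: float
    sigma2_resid: float
    theta: float
    loglik: float
    converged: bool
    boundary: bool                   # random-intercept variance hit zero
    n_obs: int
    n_groups: int
    exog_names: tuple[str, ...]
    design: np.ndarray = field(repr=False)
    response: np.ndarray = field(repr=False)
    group_codes: np.ndarray = field(repr=False)
    group_labels: tuple[str, ...] = field(repr=False)
    row_ids: tuple[str, ...] = field(repr=False)
    vcov: np.ndarray = field(repr=False)

    @property
    def fitted_fixed(self) -> np.ndarray:
        """Fixed-effects linear predictor X @ b over the analysis rows."""
        return self.design @ self.params.to_numpy()

    def conf_int(self, level: float = 0.95) -> pd.DataFrame:
        z = stats.norm.ppf(0.5 + level / 2.0)
        lo = self.params - z * self.bse
        hi = self.params + z * self.bse
        return pd.DataFrame({"lower": lo, "upper": hi})


def _coerce_numeric(col: pd.Series, name: str) -> np.ndarray:
    if pd.api.types.is_numeric_dtype(col):
        return col.to_numpy(dtype=float)
    levels = sorted(col.dropna().unique())
    if len(levels) == 2:  # binary factor -> 0/1 by sorted level order
        return (col == levels[1]).astype(float).to_numpy()
    raise ValidationError(
        f"column {name!r} is non-numeric with {len(levels)} levels; "
        "only binary factors are coded automatically")


def build_design(data: pd.DataFrame, spec: ModelSpec):
    """Complete-case design matrix, response, and group codes for a spec."""
    missing = [c for c in spec.columns if c not in data.columns]
    if missing:
        raise ValidationError(f"columns absent from data: {missing}")
    sub = data.loc[:, list(dict.fromkeys(spec.columns))].dropna()
    if sub.empty:
        raise CohortSizeError("no complete cases for the model columns")

    y = _coerce_numeric(sub[spec.response], spec.response)
    cols = [np.ones(len(sub))]
    names = ["(Intercept)"]
    term_arrays: dict[str, np.ndarray] = {}
    for t in spec.terms:
        term_arrays[t] = _coerce_numeric(sub[t], t)
        cols.append(term_arrays[t])
        names.append(t)
    for a, b in spec.interactions:
        xa = term_arrays.get(a, _coerce_numeric(sub[a], a))
        xb = term_arrays.get(b, _coerce_numeric(sub[b], b))
        cols.append(xa * xb)
        names.append(f"{a}:{b}")
    X = np.column_stack(cols)

    codes, labels = pd.factorize(sub[spec.group], sort=True)
    if len(labels) < 2:
        raise CohortSizeError(
            f"grouping factor {spec.group!r} has {len(labels)} level(s); "
            "need >= 2")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise RankError("design matrix is rank deficient (collinear terms)")
    row_ids = tuple(str(i) for i in sub.index)
    return X, np.asarray(y), names, codes, tuple(str(l) for l in labels), row_ids


class _Profile:
    """Profiled -2 log-likelihood in the variance ratio theta."""

    def __init__(self, X, y, codes, n_groups, method):
        self.X, self.y, self.method = X, y, method
        self.n, self.p = X.shape
        self.ng = np.bincount(codes, minlength=n_groups).astype(float)
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        self.Sx = np.zeros((n_groups, self.p))
        np.add.at(self.Sx, codes, X)
        self.Sy = np.bincount(codes, weights=y, minlength=n_groups)

    def solve(self, theta: float):
        c = theta / (1.0 + theta * self.ng)
        XtWX = self.XtX - (self.Sx * c[:, None]).T @ self.Sx
        XtWy = self.Xty - self.Sx.T @ (c * self.Sy)
        try:
            beta = np.linalg.solve(XtWX, XtWy)
        except np.linalg.LinAlgError as exc:
            raise RankError(f"singular weighted design at theta={theta}") from exc
        sr = self.Sy - self.Sx @ beta
        rr = self.yty - 2.0 * beta @ self.Xty + beta @ self.XtX @ beta
        rwr = rr - float(np.sum(c * sr ** 2))
        return beta, XtWX, max(rwr, 0.0)

    def neg2ll(self, theta: float) -> float:
        _, XtWX, rwr = self.solve(theta)
        logdet_v = float(np.sum(np.log1p(theta * self.ng)))
        n, p = self.n, self.p
        if rwr <= 0:
            return np.inf
        if self.method == "ML":
            s2 = rwr / n
            return n * np.log(2.0 * np.pi * s2) + logdet_v + n
        s2 = rwr / (n - p)
        sign, logdet_x = np.linalg.slogdet(XtWX)
        if sign <= 0:
            return np.inf
        return ((n - p) * np.log(2.0 * np.pi * s2) + logdet_v
                + logdet_x + (n - p))


def fit_lmm(data: pd.DataFrame, spec: ModelSpec, method: str = "ML") -> LmmFit:
    """Fit the mixed model by deterministic profiled optimisation.

    Complete cases on the model columns are used; rows can be pre-filtered
    by the caller when several fits must share identical rows (the
    likelihood-ratio machinery requires that).
    """
    if method not in ("ML", "REML"):
        raise ValidationError(f"method must be ML or REML, got {method!r}")
    X, y, names, codes, labels, row_ids = build_design(data, spec)
    prof = _Profile(X, y, codes, len(labels), method)

    # coarse deterministic search on log(theta), then bounded refinement
    grid = np.concatenate([[-np.inf], np.linspace(-12.0, 12.0, 25)])
    vals = np.array([prof.neg2ll(0.0 if not np.isfinite(u) else np.exp(u))
                     for u in grid])
    if not np.isfinite(vals).any():
        raise FitError("profiled likelihood not finite anywhere on the grid")
    best = int(np.nanargmin(vals))
    if best == 0:
        theta_hat, crit = 0.0, float(vals[0])
    else:
        lo = grid[max(best - 1, 1)]
        hi = grid[min(best + 1, len(grid) - 1)]
        res = optimize.minimize_scalar(
            lambda u: prof.neg2ll(np.exp(u)), bounds=(lo, hi),
            method="bounded", options={"xatol": 1e-10})
        theta_hat, crit = float(np.exp(res.x)), float(res.fun)
        crit0 = prof.neg2ll(0.0)
        if crit0 <= crit + _BOUNDARY_TOL:
            theta_hat, crit = 0.0, float(crit0)

    beta, XtWX, rwr = prof.solve(theta_hat)
    n, p = prof.n, prof.p
    s2_resid = rwr / (n if method == "ML" else n - p)
    s2_group = theta_hat * s2_resid
    vcov = s2_resid * np.linalg.inv(XtWX)
    bse = np.sqrt(np.diag(vcov))
    boundary = theta_hat <= _BOUNDARY_TOL
    if boundary:
        log.info("random-intercept variance fitted at the zero boundary")

    return LmmFit(
        spec=spec, method=method,
        params=pd.Series(beta, index=names),
        bse=pd.Series(bse, index=names),
        sigma2_group=float(s2_group), sigma2_resid=float(s2_resid),
        theta=float(theta_hat), loglik=float(-0.5 * crit),
        converged=True, boundary=boundary,
        n_obs=n, n_groups=len(labels),
        exog_names=tuple(names), design=X, response=y,
        group_codes=codes, group_labels=labels, row_ids=row_ids,
        vcov=vcov,
    )


def lrt_compare(full: LmmFit, null: LmmFit) -> float:
    """Likelihood-ratio p-value for nested ML fits on identical rows."""
    if full.method != "ML" or null.method != "ML":
        raise NestingError("likelihood-ratio tests require ML fits; refit")
    if full.n_obs != null.n_obs or not np.array_equal(full.response,
                                                     null.response):
        raise NestingError("fits use different rows/responses")
    if not set(null.exog_names) <= set(full.exog_names):
        raise NestingError("null model is not nested in the full model")
    df = len(full.exog_names) - len(null.exog_names)
    if df < 1:
        raise NestingError("full model adds no fixed-effect terms")
    stat = max(0.0, 2.0 * (full.loglik - null.loglik))
    return float(stats.chi2.sf(stat, df))


def nakagawa_r2(fit_or_components) -> R2Pair:
    """Marginal and conditional variance-explained of a mixed model.

    Accepts a fitted model, or a ``(var_fixed, var_group, var_resid)``
    triple of variance components. Marginal uses the fixed part only;
    conditional adds the random-intercept variance.
    """
    if isinstance(fit_or_components, LmmFit):
        fit = fit_or_components
        if not fit.converged:
            raise FitError("R^2 requested for a non-converged fit")
        var_f = float(np.var(fit.fitted_fixed, ddof=1))
        var_a, var_e = fit.sigma2_group, fit.sigma2_resid
    else:
        var_f, var_a, var_e = (float(v) for v in fit_or_components)
    if min(var_f, var_a, var_e) < 0:
        raise ValidationError("variance components must be non-negative")
    total = var_f + var_a + var_e
    if total <= 0:
        raise DegenerateDataError("total variance is zero")
    return R2Pair(marginal=var_f / total, conditional=(var_f + var_a) / total)


# ---------------------------------------------------------------------------
# simulation-based residual diagnostics


class DiagnosticsResult(NamedTuple):
    residuals: pd.Series      # scaled residuals in [0, 1], per observation
    ks_statistic: float
    ks_pvalue: float
    trend_rho: float          # residual vs rank-transformed prediction
    trend_pvalue: float
    n_sim: int


def _keyed_rng(seed: int, tag: int, key: str) -> np.random.Generator:
    digest = hashlib.blake2b(key.encode(), digest_size=8).digest()
    return np.random.default_rng([seed, tag, int.from_bytes(digest, "big")])


def simulated_residuals(fit: LmmFit, n_sim: int = 1000,
                        seed: int = 0) -> DiagnosticsResult:
    """Scaled residuals from unconditional simulation of the fitted model.

    Each observation's residual is the (tie-randomised) proportion of
    ``n_sim`` simulated responses falling below the observed value; under a
    correctly specified model they are uniform on [0, 1]. Random draws are
    keyed to group labels and row identifiers, so residuals are exactly
    equivariant under row permutations of the input data.
    """
    if n_sim < 100:
        raise ValidationError(f"n_sim must be >= 100, got {n_sim}")
    if not fit.converged:
        raise FitError("diagnostics requested for a non-converged fit")

    sd_u = np.sqrt(fit.sigma2_group)
    sd_e = np.sqrt(fit.sigma2_resid)
    mu = fit.fitted_fixed

    u_sim = np.vstack([
        _keyed_rng(seed, 1, label).normal(0.0, 1.0, n_sim) * sd_u
        for label in fit.group_labels])            # (n_groups, n_sim)

    resid = np.empty(fit.n_obs)
    for i in range(fit.n_obs):
        rng = _keyed_rng(seed, 2, fit.row_ids[i])
        sims = mu[i] + u_sim[fit.group_codes[i]] \
            + rng.normal(0.0, 1.0, n_sim) * sd_e
        n_below = int(np.sum(sims < fit.response[i]))
        n_ties = int(np.sum(sims == fit.response[i]))
        resid[i] = (n_below + rng.uniform() * (n_ties + 1)) / (n_sim + 1)

    ks = stats.kstest(resid, "uniform")
    pred_rank = stats.rankdata(mu)
    if np.ptp(pred_rank) == 0:
        trend_rho, trend_p = 0.0, 1.0
    else:
        trend = stats.spearmanr(pred_rank, resid)
        trend_rho, trend_p = float(trend.statistic), float(trend.pvalue)
    return DiagnosticsResult(
        residuals=pd.Series(resid, index=list(fit.row_ids)),
        ks_statistic=float(ks.statistic), ks_pvalue=float(ks.pvalue),
        trend_rho=trend_rho, trend_pvalue=trend_p, n_sim=n_sim)


# ---------------------------------------------------------------------------
# multiple-testing adjustment


def adjust_pvalues(pvalues: Sequence[float], method: str) -> np.ndarray:
    """Bonferroni or Benjamini-Hochberg adjustment, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    if method == "bonferroni":
        return np.minimum(1.0, m * p)
    if method == "bh_fdr":
        order = np.argsort(p, kind="stable")
        ranked = p[order] * m / np.arange(1, m + 1)
        adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty(m)
        out[order] = np.minimum(1.0, adjusted)
        return out
    raise ValidationError(f"unknown adjustment method {method!r}")
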