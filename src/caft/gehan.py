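"""Rank-based (Gehan) estimation of the censored log-linear model.

For one taxon with censored response ``tau`` and event indicator
``delta``, the regression coefficient ``beta`` of ``tau`` on centered
covariates ``X`` is estimated by the Gehan-weighted rank estimating
function

    S(beta) = sum_{i,i'} delta_i 1{e_i <~ e_i'} (X_i - X_i')

with residuals ``e_i = tau_i - X_i beta`` and the tie-splitting
indicator ``1{a <~ b} = (1{a < b} + 1{a <= b}) / 2``.  ``S`` is the
negative subgradient of the convex, piecewise-linear Gehan objective

    G(beta) = sum_{i,i'} delta_i max(0, e_i' - e_i),

so estimation is a convex minimization.  ``G`` is minimized exactly:

* one free coefficient: the subgradient of ``G`` along the coefficient
  is a nondecreasing step function of the parameter; we sort the kink
  locations and walk the cumulative slope to its sign change (the
  midpoint of a flat optimal interval is reported);
* several free coefficients: ``G`` is rewritten as a least absolute
  deviations problem over the ``delta_i = 1`` pairwise differences plus
  one large pseudo-observation absorbing the linear part, solved by
  median quantile regression and polished by exact coordinate-wise line
  searches.

Both routes are deterministic; no randomness enters estimation.

Sign convention: ``beta`` here is the coefficient of the *negative* log
relative abundance, so a covariate that increases the abundance of a
taxon has a negative coefficient at this level.  The pipeline reports
effects on the log-abundance scale (negated) to end users.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .censoring import CensoredTaxon
from .exceptions import DesignError, NotEstimableError

__all__ = [
    "DesignMatrix",
    "GehanFit",
    "SolverOptions",
    "rank_matrix",
    "gehan_score",
    "gehan_objective",
    "fit_unrestricted",
    "fit_restricted",
    "estimate_intercept_km",
]


@dataclass
class DesignMatrix:
    """Column-centered covariate matrix without an intercept column.

    The AFT model carries an explicit taxon-specific intercept, so the
    design must not contain a constant column and every column must sum
    to zero (the rank score is invariant to constant columns anyway,
    but centering keeps the variance formula simple).
    """

    X: np.ndarray
    covariate_names: Sequence[str] = None
    interest_indices: Sequence[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.X.ndim != 2:
            raise DesignError("X must be 2-D")
        n, k = self.X.shape
        if self.covariate_names is None:
            self.covariate_names = [f"x{j + 1}" for j in range(k)]
        if len(self.covariate_names) != k:
            raise DesignError("covariate_names length mismatch")
        col_sums = self.X.sum(axis=0)
        if np.any(np.abs(col_sums) > 1e-8 * max(n, 1)):
            raise DesignError("columns of X must be centered (sum to zero)")
        if np.any(np.ptp(self.X, axis=0) == 0):
            raise DesignError("X contains a constant column")
        if np.linalg.matrix_rank(self.X) < k:
            raise DesignError("X is rank deficient")
        self.interest_indices = list(self.interest_indices)

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_covariates(self) -> int:
        return self.X.shape[1]


@dataclass
class GehanFit:
    """Result of minimizing the Gehan objective for one taxon."""

    beta_hat: np.ndarray
    objective_value: float
    score_at_solution: np.ndarray
    converged: bool
    n_effective: int
    lambda_hat: Optional[np.ndarray] = None
    message: str = ""


@dataclass
class SolverOptions:
    """Tolerances for the convex minimization (all deterministic)."""

    max_iter: int = 2000
    param_tol: float = 1e-8
    objective_tol: float = 1e-10
    polish_sweeps: int = 2


def rank_matrix(residuals: np.ndarray, delta: np.ndarray) -> np.ndarray:
    """Gehan comparison matrix ``R[i, i'] = delta_i 1{e_i <~ e_i'}``.

    Ties contribute 1/2; the diagonal is ``delta_i / 2``.  Dense O(N^2).
    """
    e = np.asarray(residuals, dtype=float)
    d = np.asarray(delta, dtype=float)
    lt = (e[:, None] < e[None, :]).astype(float)
    le = (e[:, None] <= e[None, :]).astype(float)
    return d[:, None] * 0.5 * (lt + le)


def _row_col_gap(residuals: np.ndarray, delta: np.ndarray) -> np.ndarray:
    """The vector a_i = R_{i+} - R_{+i} without materializing R twice."""
    r = rank_matrix(residuals, delta)
    return r.sum(axis=1) - r.sum(axis=0)


def gehan_score(beta: np.ndarray, taxon: CensoredTaxon, X: DesignMatrix) -> np.ndarray:
    """Gehan estimating function S(beta) = sum_i (R_{i+} - R_{+i}) X_i."""
    Xm = X.X if isinstance(X, DesignMatrix) else np.atleast_2d(np.asarray(X, float))
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    e = taxon.tau - Xm @ beta
    a = _row_col_gap(e, taxon.delta)
    return a @ Xm


def gehan_objective(beta: np.ndarray, taxon: CensoredTaxon, X: DesignMatrix) -> float:
    """Convex Gehan objective G(beta) = sum_{i,i'} delta_i max(0, e_i' - e_i)."""
    Xm = X.X if isinstance(X, DesignMatrix) else np.atleast_2d(np.asarray(X, float))
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    e = taxon.tau - Xm @ beta
    d = np.asarray(taxon.delta, dtype=float)
    return float((d[:, None] * np.maximum(0.0, e[None, :] - e[:, None])).sum())


def _gehan_pairs(tau: np.ndarray, delta: np.ndarray, X: np.ndarray):
    """Pairwise representation of G: G(beta) = const + sum_p max(0, d_p - z_p beta).

    Pairs run over (i uncensored, i' any); pairs whose covariate
    difference is exactly zero contribute a beta-independent constant.
    """
    unc = np.flatnonzero(np.asarray(delta) == 1)
    if unc.size == 0:
        raise NotEstimableError("every observation is censored")
    d = (tau[None, :] - tau[unc, None]).ravel()
    Z = (X[None, :, :] - X[unc, None, :]).reshape(-1, X.shape[1])
    live = ~np.all(Z == 0.0, axis=1)
    const = float(np.maximum(0.0, d[~live]).sum())
    return d[live], Z[live], const


def _minimize_1d(d: np.ndarray, g: np.ndarray):
    """Exact minimizer of f(t) = sum_p max(0, d_p - g_p t).

    The derivative is a nondecreasing step function with jumps |g_p| at
    the kinks t_p = d_p / g_p; we locate its sign change.  Returns
    ``(t, flat, ok)`` where ``flat`` is True when the minimum is
    attained on a nondegenerate interval (the midpoint is returned) and
    ``ok`` is False when the objective carries no slope information.
    """
    nz = g != 0.0
    d, g = d[nz], g[nz]
    if d.size == 0:
        return 0.0, True, False
    kinks = d / g
    slopes = np.abs(g)
    order = np.argsort(kinks, kind="stable")
    kinks, slopes = kinks[order], slopes[order]
    s0 = -g[g > 0].sum()  # slope at t -> -inf, always <= 0
    cum = s0 + np.cumsum(slopes)
    tol = 1e-12 * slopes.sum()
    if s0 >= -tol:  # no descending part: minimum on (-inf, first kink]
        return float(kinks[0]), True, False
    idx = int(np.searchsorted(cum >= -tol, True))
    if idx >= len(kinks):  # pragma: no cover - cannot happen (cum ends >= 0)
        return float(kinks[-1]), True, False
    if cum[idx] <= tol and idx + 1 < len(kinks):
        return float(0.5 * (kinks[idx] + kinks[idx + 1])), True, True
    if cum[idx] <= tol:
        return float(kinks[idx]), True, False
    return float(kinks[idx]), False, True


def _pair_objective(beta: np.ndarray, d: np.ndarray, Z: np.ndarray) -> float:
    return float(np.maximum(0.0, d - Z @ beta).sum())


def _polish_coordinates(beta: np.ndarray, d: np.ndarray, Z: np.ndarray, sweeps: int) -> np.ndarray:
    """Exact coordinate-wise line searches of the pairwise objective."""
    beta = beta.copy()
    for _ in range(sweeps):
        moved = False
        for k in range(Z.shape[1]):
            resid = d - Z @ beta + Z[:, k] * beta[k]
            t, _, ok = _minimize_1d(resid, Z[:, k])
            if ok and abs(t - beta[k]) > 1e-12 * (1.0 + abs(beta[k])):
                beta[k] = t
                moved = True
        if not moved:
            break
    return beta


def _minimize_lad(d: np.ndarray, Z: np.ndarray, options: SolverOptions):
    """Minimize sum_p max(0, d_p - z_p beta) for K >= 2 free coefficients.

    Uses the identity max(0, u) = (|u| + u) / 2: the sum of absolute
    residuals is handled by median quantile regression and the linear
    remainder is absorbed by a single pseudo-observation with a large
    response, a standard device for Gehan-type objectives.
    """
    import statsmodels.api as sm

    big_m = 10.0 * (np.abs(d).sum() + 1.0)
    y = np.concatenate([d, [big_m]])
    Xa = np.vstack([Z, Z.sum(axis=0)])
    ok = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.QuantReg(y, Xa).fit(
                q=0.5, max_iter=options.max_iter, p_tol=options.param_tol
            )
        beta = np.asarray(res.params, dtype=float)
    except Exception:  # singular weighting step etc.: fall back to sweeps
        beta = np.zeros(Z.shape[1])
        ok = False
    beta = _polish_coordinates(beta, d, Z, options.polish_sweeps)
    if not ok:
        beta = _polish_coordinates(beta, d, Z, 25)
    return beta, ok


def fit_unrestricted(
    taxon: CensoredTaxon,
    X: DesignMatrix,
    options: Optional[SolverOptions] = None,
) -> GehanFit:
    """Minimize the Gehan objective over all K coefficients."""
    options = options or SolverOptions()
    Xm = X.X if isinstance(X, DesignMatrix) else np.atleast_2d(np.asarray(X, float))
    tau = np.asarray(taxon.tau, dtype=float)
    delta = np.asarray(taxon.delta)
    d, Z, const = _gehan_pairs(tau, delta, Xm)
    k = Xm.shape[1]
    if d.size == 0:
        raise NotEstimableError("no informative pairs (no covariate variation among comparisons)")
    if k == 1:
        t, flat, ok = _minimize_1d(d, Z[:, 0])
        beta = np.array([t])
        converged = ok
        message = "" if ok else "objective flat along the covariate"
    else:
        beta, converged = _minimize_lad(d, Z, options)
        message = "" if converged else "quantile-regression step failed; coordinate sweeps used"
    obj = const + _pair_objective(beta, d, Z)
    score = gehan_score(beta, CensoredTaxon(tau=tau, delta=delta), Xm)
    return GehanFit(
        beta_hat=beta,
        objective_value=obj,
        score_at_solution=score,
        converged=converged,
        n_effective=int((delta == 1).sum()),
        message=message,
    )


def fit_restricted(
    taxon: CensoredTaxon,
    X: DesignMatrix,
    contrast,
    options: Optional[SolverOptions] = None,
) -> GehanFit:
    """Minimize the Gehan objective subject to ``Gamma beta = b``.

    The feasible set is the affine family ``beta = Gamma^- b +
    Lambda^- lambda`` with ``lambda`` free, so the restricted problem is
    again an unrestricted Gehan problem in ``lambda`` with response
    offset ``X Gamma^- b`` and design ``X Lambda^-``.  When the null is
    simple (``Lambda`` empty) the solution is ``Gamma^- b`` directly.
    """
    options = options or SolverOptions()
    Xm = X.X if isinstance(X, DesignMatrix) else np.atleast_2d(np.asarray(X, float))
    tau = np.asarray(taxon.tau, dtype=float)
    delta = np.asarray(taxon.delta)
    gamma_pinv = np.linalg.pinv(contrast.Gamma)
    beta0 = gamma_pinv @ np.atleast_1d(contrast.b)
    if contrast.Lambda.size == 0:
        beta = beta0
        obj = gehan_objective(beta, taxon, Xm)
        score = gehan_score(beta, taxon, Xm)
        return GehanFit(
            beta_hat=beta,
            objective_value=obj,
            score_at_solution=score,
            converged=True,
            n_effective=int((delta == 1).sum()),
            lambda_hat=np.zeros(0),
        )
    lam_pinv = contrast.Lambda.T  # rows orthonormal => pinv is the transpose
    W = Xm @ lam_pinv
    offset_taxon = CensoredTaxon(tau=tau - Xm @ beta0, delta=delta, taxon_id=taxon.taxon_id)
    inner = fit_unrestricted(offset_taxon, W, options=options)
    beta = beta0 + lam_pinv @ inner.beta_hat
    obj = gehan_objective(beta, taxon, Xm)
    score = gehan_score(beta, taxon, Xm)
    return GehanFit(
        beta_hat=beta,
        objective_value=obj,
        score_at_solution=score,
        converged=inner.converged,
        n_effective=inner.n_effective,
        lambda_hat=inner.beta_hat,
        message=inner.message,
    )


def estimate_intercept_km(taxon: CensoredTaxon, X: DesignMatrix, beta: np.ndarray) -> float:
    """Intercept as the Kaplan-Meier median of the residuals.

    Fits the product-limit survival curve of ``tau - X beta`` with the
    taxon's censoring indicators and returns the smallest residual at
    which the curve drops to 0.5 or below.  Returns ``nan`` when
    censoring is too heavy for the curve to reach 0.5.
    """
    from lifelines import KaplanMeierFitter

    Xm = X.X if isinstance(X, DesignMatrix) else np.atleast_2d(np.asarray(X, float))
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    resid = taxon.tau - Xm @ beta
    if not np.any(np.asarray(taxon.delta) == 1):
        raise NotEstimableError("no uncensored residuals")
    km = KaplanMeierFitter()
    km.fit(resid, event_observed=np.asarray(taxon.delta))
    med = km.median_survival_time_
    return float(med) if np.isfinite(med) else float("nan")
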