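"""Variance estimation and restricted score tests for the Gehan score.

Inference is score-based throughout: the Gehan estimating function is a
step function of ``beta``, so Wald-type tests would require smoothing
its derivative, whereas the score evaluated at the null-restricted
estimate needs only a variance.  The variance estimator is the *rank*
estimator

    sigma2 = (1/N) sum_i (R_{i+} - R_{+i})^2,      V = sigma2 * Xc' Xc,

where ``R`` is the Gehan comparison matrix at the restricted fit and
``Xc`` is the column-centered design.  This exploits the approximate
independence, at the estimate, between the rank information in ``R``
and the residuals, and matches the permutation variance of
``sum_i a_i X_i`` for fixed scores ``a_i = R_{i+} - R_{+i}``.

For a composite null ``H0: Gamma beta = b`` (``Gamma`` of full row rank
d < K) the nuisance directions are spanned by the orthonormal rows of
``Lambda`` (``Gamma Lambda' = 0``).  With ``S_gamma = Gamma S`` at the
restricted fit, the statistic is the Schur-complement quadratic form

    T = S_gamma' [V_gg - V_gl V_ll^{-1} V_lg]^{-1} S_gamma,

referred to chi-square with d degrees of freedom; for a simple null
(``Lambda`` empty) it reduces to ``S' V^{-1} S`` with d = K.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import linalg, stats

from .censoring import CensoredTaxon
from .exceptions import CaftError
from .gehan import DesignMatrix, GehanFit, SolverOptions, fit_restricted, rank_matrix

__all__ = [
    "ContrastSpec",
    "ScoreTestResult",
    "contrast_complement",
    "interest_contrast",
    "rank_sigma2",
    "rank_variance",
    "score_test",
    "cox_variance",
]

#: pseudo-inverse relative tolerance on singular values
_PINV_RTOL = 1e-12
#: condition number above which nuisance-block inversion warns
_COND_WARN = 1e10


@dataclass
class ContrastSpec:
    """Null hypothesis ``Gamma beta = b`` plus its nuisance complement.

    ``Lambda`` has orthonormal rows spanning the null space of
    ``Gamma``; it is empty (shape ``(0, K)``) for a simple null.
    """

    Gamma: np.ndarray
    b: np.ndarray
    Lambda: np.ndarray = None

    def __post_init__(self) -> None:
        self.Gamma = np.atleast_2d(np.asarray(self.Gamma, dtype=float))
        d, k = self.Gamma.shape
        if np.linalg.matrix_rank(self.Gamma) < d:
            raise CaftError("Gamma must have full row rank")
        self.b = np.atleast_1d(np.asarray(self.b, dtype=float))
        if self.b.shape != (d,):
            raise CaftError(f"b must have length {d}")
        if self.Lambda is None:
            self.Lambda = _null_space_rows(self.Gamma)
        else:
            self.Lambda = np.asarray(self.Lambda, dtype=float).reshape(-1, k)
        if self.Lambda.size:
            if np.max(np.abs(self.Gamma @ self.Lambda.T)) > 1e-10:
                raise CaftError("Gamma and Lambda are not orthogonal")
            gram = self.Lambda @ self.Lambda.T
            if np.max(np.abs(gram - np.eye(self.Lambda.shape[0]))) > 1e-8:
                raise CaftError("Lambda rows must be orthonormal")

    @property
    def d(self) -> int:
        return self.Gamma.shape[0]

    @property
    def K(self) -> int:
        return self.Gamma.shape[1]


@dataclass
class ScoreTestResult:
    """Restricted score test output for one taxon."""

    taxon_id: object
    beta_restricted: np.ndarray
    score: np.ndarray
    variance: np.ndarray
    statistic: float
    df: int
    p_value: float
    converged: bool = True
    fit: Optional[GehanFit] = field(default=None, repr=False)


def _null_space_rows(Gamma: np.ndarray) -> np.ndarray:
    """Canonical orthonormal basis of the null space of Gamma, as rows.

    SVD-based; each row is signed so that its first entry of largest
    magnitude is positive, making the basis deterministic.
    """
    ns = linalg.null_space(Gamma, rcond=_PINV_RTOL)  # K x (K-d), orthonormal cols
    rows = ns.T
    for r in rows:
        lead = np.argmax(np.abs(r) > 1e-12) if np.any(np.abs(r) > 1e-12) else 0
        if r[lead] < 0:
            r *= -1.0
    return rows


def contrast_complement(Gamma: np.ndarray, b=None) -> ContrastSpec:
    """Build a :class:`ContrastSpec` with a canonical nuisance basis."""
    Gamma = np.atleast_2d(np.asarray(Gamma, dtype=float))
    if b is None:
        b = np.zeros(Gamma.shape[0])
    return ContrastSpec(Gamma=Gamma, b=b, Lambda=_null_space_rows(Gamma))


def interest_contrast(n_covariates: int, interest_indices, b=None) -> ContrastSpec:
    """Contrast selecting the given design columns: Gamma = rows of I_K."""
    idx = list(interest_indices)
    Gamma = np.eye(n_covariates)[idx]
    return contrast_complement(Gamma, b=b)


def rank_sigma2(R: np.ndarray) -> float:
    """Rank variance scale: (1/N) sum_i (R_{i+} - R_{+i})^2."""
    R = np.asarray(R, dtype=float)
    a = R.sum(axis=1) - R.sum(axis=0)
    return float(a @ a / R.shape[0])


def rank_variance(sigma2: float, X) -> np.ndarray:
    """Rank estimator of Var[S]: sigma2 * (X - Xbar)' (X - Xbar)."""
    Xm = X.X if isinstance(X, DesignMatrix) else np.atleast_2d(np.asarray(X, float))
    Xc = Xm - Xm.mean(axis=0)
    return sigma2 * (Xc.T @ Xc)


def score_test(
    taxon: CensoredTaxon,
    X: DesignMatrix,
    contrast: ContrastSpec,
    options: Optional[SolverOptions] = None,
    restricted_fit: Optional[GehanFit] = None,
) -> ScoreTestResult:
    """Restricted score test of ``H0: Gamma beta = b`` for one taxon."""
    Xm = X.X if isinstance(X, DesignMatrix) else np.atleast_2d(np.asarray(X, float))
    fit = restricted_fit if restricted_fit is not None else fit_restricted(
        taxon, Xm, contrast, options=options
    )
    e = taxon.tau - Xm @ fit.beta_hat
    R = rank_matrix(e, taxon.delta)
    a = R.sum(axis=1) - R.sum(axis=0)
    S = a @ Xm
    sigma2 = float(a @ a / len(a))
    V = rank_variance(sigma2, Xm)
    Gamma, Lam = contrast.Gamma, contrast.Lambda
    S_g = Gamma @ S
    if Lam.size == 0:
        middle = np.linalg.pinv(V, rcond=_PINV_RTOL)
        stat = float(S @ middle @ S)
        df = contrast.K
    else:
        V_gg = Gamma @ V @ Gamma.T
        V_gl = Gamma @ V @ Lam.T
        V_ll = Lam @ V @ Lam.T
        if np.linalg.cond(V_ll) > _COND_WARN:
            warnings.warn("nuisance variance block is ill conditioned", RuntimeWarning)
        schur = V_gg - V_gl @ np.linalg.pinv(V_ll, rcond=_PINV_RTOL) @ V_gl.T
        stat = float(S_g @ np.linalg.pinv(schur, rcond=_PINV_RTOL) @ S_g)
        df = contrast.d
    degenerate = (Lam.size == 0 and not np.any(np.abs(V) > 0)) or (
        Lam.size != 0 and not np.any(np.abs(schur) > 0)
    )
    if degenerate and np.any(np.abs(S_g) > 1e-8):
        p = float("nan")  # singular variance with a nonzero score: no calibration
    else:
        p = float(stats.chi2.sf(stat, df)) if stat > 0 else 1.0
    return ScoreTestResult(
        taxon_id=taxon.taxon_id,
        beta_restricted=fit.beta_hat,
        score=S,
        variance=V,
        statistic=max(stat, 0.0),
        df=df,
        p_value=p,
        converged=fit.converged,
        fit=fit,
    )


def cox_variance(taxon: CensoredTaxon, X: DesignMatrix, beta: np.ndarray) -> np.ndarray:
    """Martingale-based (Cox-model) variance of the Gehan score.

    Not implemented: the rank estimator is the default and the
    recommended choice; see Kalbfleisch & Prentice (2002, ch. 7) for
    the martingale representation this would follow.
    """
    raise NotImplementedError(
        "Cox-model score variance is not provided; use the rank estimator"
    )
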