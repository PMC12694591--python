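"""Compositional null reference: the median of per-taxon coefficients.

Only differences of coefficients across taxa are identifiable in a
compositional model, so each taxon is tested against a reference value
shared by all taxa.  Under the sparsity-of-signal assumption — far
fewer than half of the taxa truly respond to the covariates — the
median of the per-taxon estimates is the coefficient of a null taxon
and serves as the null value ``b = Gamma beta_med``.  The reference is
treated as a fixed parameter in every test; this is justified when it
is estimated from many taxa, and a warning is emitted when few taxa
contribute.

For a single tested component the reference is the ordinary sample
median.  For d > 1 components it is the Hettmansperger-Randles (HR)
affine-equivariant spatial median: the transformation-retransformation
M-estimate solving, jointly over location ``theta`` and a scatter
transform ``A``,

    ave[ s_i ] = 0   and   ave[ s_i s_i' ] = I_d / d,
    s_i = A (x_i - theta) / || A (x_i - theta) ||.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .exceptions import CaftError
from .inference import ContrastSpec

__all__ = [
    "CoefficientPanel",
    "hr_spatial_median",
    "spatial_median",
    "build_null_rhs",
]

#: below this many contributing taxa the fixed-reference approximation is shaky
SMALL_PANEL_WARNING = 50


@dataclass
class CoefficientPanel:
    """Unrestricted coefficient estimates for all taxa (rows = taxa)."""

    betas: np.ndarray
    fitted_flags: np.ndarray = None
    taxon_ids: Sequence = None

    def __post_init__(self) -> None:
        self.betas = np.atleast_2d(np.asarray(self.betas, dtype=float))
        if self.fitted_flags is None:
            self.fitted_flags = np.all(np.isfinite(self.betas), axis=1)
        self.fitted_flags = np.asarray(self.fitted_flags, dtype=bool)
        if len(self.fitted_flags) != self.betas.shape[0]:
            raise CaftError("fitted_flags length mismatch")

    def valid_rows(self) -> np.ndarray:
        ok = self.fitted_flags & np.all(np.isfinite(self.betas), axis=1)
        return self.betas[ok]


def hr_spatial_median(
    points: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 500,
    return_transform: bool = False,
):
    """Hettmansperger-Randles affine-equivariant spatial median.

    Iterates the transformation-retransformation fixed point described
    in the module docstring, starting from the componentwise median and
    the identity transform.  Deterministic.  Falls back to the
    componentwise median (with a warning) if the iteration fails to
    converge in ``max_iter`` steps.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    n, d = pts.shape
    if d == 1:
        theta = np.array([np.median(pts[:, 0])])
        return (theta, np.eye(1)) if return_transform else theta
    theta = np.median(pts, axis=0)
    A = np.eye(d)
    converged = False
    for _ in range(max_iter):
        Z = (pts - theta) @ A.T
        norms = np.linalg.norm(Z, axis=1)
        keep = norms > 1e-12
        if keep.sum() < d + 1:
            break
        w = 1.0 / norms[keep]
        step = (Z[keep] * w[:, None]).sum(axis=0) / w.sum()
        theta_new = theta + np.linalg.solve(A, step)
        signs = Z[keep] / norms[keep][:, None]
        U = signs.T @ signs / keep.sum()
        evals, evecs = np.linalg.eigh(d * U)
        B = evecs @ np.diag(1.0 / np.sqrt(np.maximum(evals, 1e-12))) @ evecs.T
        A_new = B @ A
        A_new /= np.abs(np.linalg.det(A_new)) ** (1.0 / d)
        shift = np.linalg.norm(theta_new - theta) / (1.0 + np.linalg.norm(theta))
        scatter_shift = np.linalg.norm(A_new - A)
        theta, A = theta_new, A_new
        if max(shift, scatter_shift) < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            "HR spatial median did not converge; using the componentwise median",
            RuntimeWarning,
        )
        theta = np.median(pts, axis=0)
    return (theta, A) if return_transform else theta


def spatial_median(panel: CoefficientPanel, dims: Optional[Sequence[int]] = None) -> np.ndarray:
    """Median of the valid panel rows over the selected components.

    Scalar (ordinary) median for one component, HR spatial median for
    several.  Requires at least three valid rows.
    """
    rows = panel.valid_rows()
    if rows.shape[0] < 3:
        raise CaftError(
            f"need at least 3 taxa with valid fits to form a reference, got {rows.shape[0]}"
        )
    if dims is not None:
        rows = rows[:, list(dims)]
    if rows.shape[0] < SMALL_PANEL_WARNING:
        warnings.warn(
            f"reference median computed from only {rows.shape[0]} taxa; "
            "treating it as fixed may understate uncertainty",
            RuntimeWarning,
        )
    if rows.shape[1] == 1:
        return np.array([np.median(rows[:, 0])])
    return hr_spatial_median(rows)


def build_null_rhs(panel: CoefficientPanel, contrast: ContrastSpec) -> ContrastSpec:
    """Set the null right-hand side to the median of ``Gamma beta_j``.

    Each valid taxon contributes its projection ``Gamma beta_j``; the
    (spatial) median of these d-vectors becomes ``b``.  The reference
    enters every test as a fixed constant.
    """
    rows = panel.valid_rows()
    if rows.shape[0] < 3:
        raise CaftError("need at least 3 valid taxa to build the null reference")
    proj = rows @ contrast.Gamma.T
    b = spatial_median(CoefficientPanel(betas=proj))
    return ContrastSpec(Gamma=contrast.Gamma, b=b, Lambda=contrast.Lambda)
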