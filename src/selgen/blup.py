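"""Pedigree and genomic BLUP as Gaussian posteriors.

At known variance components, BLUP of breeding values coincides with the
posterior mean of the conjugate Gaussian model ``y = u + e`` with
``u ~ N(0, K sigma2_u)``, ``e ~ N(0, I sigma2_e)``:

    mean = (I + (sigma2_e/sigma2_u) K^-1)^-1 y = G [R + G]^-1 y
    cov  = (I + (sigma2_e/sigma2_u) K^-1)^-1 sigma2_e

with ``G = K sigma2_u`` and ``R = I sigma2_e``.  The module also provides
single-kernel maximum-likelihood variance components (via eigendecomposition
of K and 1-D optimization of the variance ratio) and the post-selection
moments of the BLUP, which is a fixed linear map of the data and therefore
inherits whatever moments selection gives the phenotypes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .core import RelationshipMatrix, VarianceComponents, nearest_psd

__all__ = [
    "BlupPosterior",
    "blup_posterior",
    "ml_single_kernel",
    "blup_moments_under_selection",
    "blup_map",
]

_MIN_EIG = 1e-10


@dataclass
class BlupPosterior:
    """Posterior (mean, covariance) of breeding values at known variances."""

    mean: np.ndarray
    cov: np.ndarray
    vc: VarianceComponents | None = None

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.cov = np.asarray(self.cov, dtype=float)
        if self.cov.shape != (len(self.mean), len(self.mean)):
            raise ValueError("cov must be square and match mean dimension")
        if not np.allclose(self.cov, self.cov.T, atol=1e-8):
            raise ValueError("posterior covariance must be symmetric")

    @property
    def sd(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.cov), 0, None))


def _check_K(K: RelationshipMatrix) -> np.ndarray:
    M = K.K
    w = np.linalg.eigvalsh(M)
    if w[0] < _MIN_EIG * max(w[-1], 1.0):
        raise np.linalg.LinAlgError(
            "relationship matrix is singular; repair it with nearest_psd "
            "(or bend it) before computing a BLUP posterior"
        )
    return M


def blup_map(K: RelationshipMatrix, vc: VarianceComponents) -> np.ndarray:
    """The BLUP smoother matrix ``M = (I + (sigma2_e/sigma2_u) K^-1)^-1``.

    Computed in the algebraically equivalent, inversion-free form
    ``sigma2_u K (sigma2_u K + sigma2_e I)^-1``.
    """
    M = _check_K(K)
    G = vc.sigma2_u * M
    V = G + vc.sigma2_e * np.eye(K.n)
    return np.linalg.solve(V.T, G.T).T  # G V^-1


def blup_posterior(
    y: np.ndarray, K: RelationshipMatrix, vc: VarianceComponents
) -> BlupPosterior:
    """Posterior of breeding values given centered phenotypes ``y``."""
    y = np.asarray(y, dtype=float)
    if len(y) != K.n:
        raise ValueError("phenotype vector does not match relationship matrix")
    M = blup_map(K, vc)
    mean = M @ y
    cov = M * vc.sigma2_e
    cov = (cov + cov.T) / 2
    return BlupPosterior(mean, cov, vc)


def ml_single_kernel(
    y: np.ndarray,
    K: RelationshipMatrix,
    ratio_bounds: tuple[float, float] = (1e-6, 1e6),
    tol: float = 1e-10,
) -> VarianceComponents:
    """Maximum-likelihood variance components for ``y ~ N(0, K su2 + I se2)``.

    Phenotypes are centered by their sample mean first (the model carries no
    fixed effects).  With ``K = U D U'`` and ``z = U'y``, the log-likelihood
    at variance ratio ``r = su2/se2`` profiles out ``se2`` in closed form,
    leaving a unimodal 1-D problem solved by bounded Brent search on
    ``log r``.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 10:
        raise ValueError("need at least 10 records for variance estimation")
    if n != K.n:
        raise ValueError("phenotype vector does not match relationship matrix")
    yc = y - y.mean()
    d, U = np.linalg.eigh(K.K)
    d = np.clip(d, 0.0, None)
    z2 = (U.T @ yc) ** 2

    def profile(log_r: float) -> tuple[float, float]:
        r = np.exp(log_r)
        v = r * d + 1.0  # eigenvalues of (r K + I)
        se2 = float(np.sum(z2 / v) / n)
        nll = 0.5 * (np.sum(np.log(v)) + n * np.log(se2) + n)
        return nll, se2

    lo, hi = np.log(ratio_bounds[0]), np.log(ratio_bounds[1])
    res = minimize_scalar(lambda lr: profile(lr)[0], bounds=(lo, hi),
                          method="bounded", options={"xatol": tol})
    if not res.success:
        raise RuntimeError(
            f"variance-ratio optimization did not converge: {res.message}; "
            f"bounds=({ratio_bounds[0]:g},{ratio_bounds[1]:g}), n={n}"
        )
    r_hat = float(np.exp(res.x))
    _, se2 = profile(res.x)
    return VarianceComponents(sigma2_u=r_hat * se2, sigma2_e=se2)


def blup_moments_under_selection(
    E_s_y: np.ndarray,
    Var_s_y: np.ndarray,
    K: RelationshipMatrix,
    vc: VarianceComponents,
) -> tuple[np.ndarray, np.ndarray]:
    """Moments of the BLUP when selection has modified the phenotype moments.

    The BLUP is the fixed linear map ``M y``; under selection
    ``E_s(M y) = M E_s(y)`` and ``Var_s(M y) = M Var_s(y) M'``.  Without
    selection (``E_s(y)=0``, ``Var_s(y)=Var(y)``) these reduce to the
    unselected sampling moments ``0`` and ``G [R+G]^-1 G``.
    """
    E_s_y = np.asarray(E_s_y, dtype=float)
    Var_s_y = np.asarray(Var_s_y, dtype=float)
    if len(E_s_y) != K.n or Var_s_y.shape != (K.n, K.n):
        raise ValueError("selection moments do not match relationship matrix")
    M = blup_map(K, vc)
    return M @ E_s_y, M @ Var_s_y @ M.T
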