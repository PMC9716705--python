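"""Selection-corrected genomic breeding values after pedigree pre-selection.

The scenario: genotyping was restricted to candidates whose pedigree BLUP
exceeded a threshold ``t``.  The posterior of the genomic breeding values of
the genotyped (selected) individuals is the selection-ignoring GBLUP Gaussian
multiplied by a correction

    f_sel(g) = sum_i log[1 - Phi(z_i)],
    z_i = (t - rho_i (sigma_ahat_i / sigma_g_i) g_i)
          / sqrt(sigma2_ahat_i (1 - sigma2_ahat_i / sigma2_g_i)),

the log-probability that each individual's pedigree BLUP exceeded the
threshold given its genomic value.  The posterior is sampled with an
independence Metropolis algorithm whose proposal is the pedigree-BLUP
posterior.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .blup import BlupPosterior, blup_posterior
from .cli_io import LOG_BLOCK, MCMCChain
from .core import RelationshipMatrix, VarianceComponents

logger = logging.getLogger("selgen")

__all__ = [
    "PreselectionModel",
    "gblup_sel",
    "preselection_log_posterior",
    "run_preselection_sampler",
]


@dataclass
class PreselectionModel:
    """All quantities needed for the pre-selection-corrected posterior.

    t
        Pedigree-BLUP selection threshold (trait units).
    rho_ga
        Correlation between the unknown genomic breeding value and the
        pedigree BLUP; a global scalar or one value per selected individual.
    sigma2_ahat_i
        Per-individual variance of the pedigree BLUP (trait-units^2).
    sigma2_g_i
        Per-individual genomic variance, ``diag(G sigma2_g)``.
    G_sel
        Genomic relationship matrix among the selected individuals.
    vc_g
        Genomic variance components (sigma2_g, sigma2_e*).
    y_sel
        Centered phenotypes of the selected individuals.
    A_sel, vc_a
        Pedigree relationship matrix among the selected individuals and the
        pedigree-model variance components, used to build the Metropolis
        proposal; optional (the GBLUP posterior is used as proposal if absent).
    """

    t: float
    rho_ga: float | np.ndarray
    sigma2_ahat_i: np.ndarray
    sigma2_g_i: np.ndarray
    G_sel: RelationshipMatrix
    vc_g: VarianceComponents
    y_sel: np.ndarray
    A_sel: RelationshipMatrix | None = None
    vc_a: VarianceComponents | None = None

    def __post_init__(self) -> None:
        m = self.G_sel.n
        self.y_sel = np.asarray(self.y_sel, dtype=float)
        self.sigma2_ahat_i = np.broadcast_to(
            np.asarray(self.sigma2_ahat_i, dtype=float), (m,)
        ).copy()
        self.sigma2_g_i = np.broadcast_to(
            np.asarray(self.sigma2_g_i, dtype=float), (m,)
        ).copy()
        self.rho_ga = np.broadcast_to(
            np.asarray(self.rho_ga, dtype=float), (m,)
        ).copy()
        if len(self.y_sel) != m:
            raise ValueError("y_sel does not match G_sel")
        if np.any((self.rho_ga <= 0) | (self.rho_ga >= 1)):
            raise ValueError("rho_ga must lie in (0, 1)")
        bad = np.where(self.sigma2_ahat_i > self.sigma2_g_i)[0]
        if bad.size:
            raise ValueError(
                "sigma2_ahat_i must not exceed sigma2_g_i (non-positive "
                f"z-denominator) for individuals {bad.tolist()[:10]}"
            )

    @property
    def m(self) -> int:
        return self.G_sel.n

    def z_denominator(self) -> np.ndarray:
        den2 = self.sigma2_ahat_i * (1 - self.sigma2_ahat_i / self.sigma2_g_i)
        bad = np.where(den2 <= 0)[0]
        if bad.size:
            raise ValueError(
                f"non-positive z-denominator for individuals {bad.tolist()[:10]}"
            )
        return np.sqrt(den2)


def gblup_sel(model: PreselectionModel) -> BlupPosterior:
    """GBLUP posterior of the selected individuals, ignoring selection."""
    return blup_posterior(model.y_sel, model.G_sel, model.vc_g)


def _z_scores(model: PreselectionModel, g: np.ndarray) -> np.ndarray:
    """z_i for one candidate vector or a matrix of candidates (rows)."""
    slope = model.rho_ga * np.sqrt(model.sigma2_ahat_i / model.sigma2_g_i)
    return (model.t - slope * g) / model.z_denominator()


def log_correction(model: PreselectionModel, g: np.ndarray) -> np.ndarray | float:
    """f_sel(g) = sum_i log[1 - Phi(z_i)]; vectorized over rows of ``g``."""
    z = _z_scores(model, np.asarray(g, dtype=float))
    out = norm.logsf(z).sum(axis=-1)
    return float(out) if out.ndim == 0 else out


def preselection_log_posterior(
    g_sel: np.ndarray, model: PreselectionModel, include_correction: bool = True
) -> float:
    """Log posterior density of ``g_sel`` up to a constant."""
    g = np.asarray(g_sel, dtype=float)
    if g.shape[-1] != model.m:
        raise ValueError("g_sel dimension does not match the selected set")
    post = gblup_sel(model)
    prec = np.linalg.inv(post.cov)  # = C~^-1 / sigma2_e*
    d = g - post.mean
    quad = -0.5 * float(d @ prec @ d)
    if include_correction:
        return quad + float(log_correction(model, g))
    return quad


def _mvn_chol_logpdf(X: np.ndarray, mean: np.ndarray, L: np.ndarray) -> np.ndarray:
    """Log density of rows of X under N(mean, L L'); constant included."""
    from scipy.linalg import solve_triangular

    d = X - mean
    w = solve_triangular(L, d.T, lower=True)
    logdet = 2 * np.sum(np.log(np.diag(L)))
    k = len(mean)
    return -0.5 * (np.sum(w**2, axis=0) + logdet + k * np.log(2 * np.pi))


def run_preselection_sampler(
    model: PreselectionModel,
    n_iter: int = 20_000,
    burn_in: int | None = None,
    seed: int = 0,
    mode: str = "full_mh",
    include_correction: bool = True,
) -> MCMCChain:
    """Independence Metropolis sampler for the pre-selection posterior.

    The proposal is the pedigree-BLUP posterior
    ``N(a~_sel, (I + (sigma2_e/sigma2_a) A_sel^-1)^-1 sigma2_e)`` when the
    model carries ``A_sel``/``vc_a``, otherwise the GBLUP posterior.  Modes:

    ``full_mh``
        Correct Metropolis-Hastings ratio: target ratio times the
        independence-proposal density ratio ``q(g_now)/q(g_prop)``.
    ``as_printed``
        The ratio exactly as the source protocol states it — quadratic term
        oriented proposal-minus-current, correction ratio
        ``(1-Phi(z_now))/(1-Phi(z_prop))``, and no proposal-density factor.

    Returns the chain (all draws kept; ``burn_in`` defaults to 20% and is
    only used for the low-acceptance diagnostic).
    """
    if mode not in ("full_mh", "as_printed"):
        raise ValueError(f"unknown mode {mode!r}")
    if burn_in is None:
        burn_in = n_iter // 5
    rng = np.random.default_rng(seed)
    m = model.m

    target = gblup_sel(model)
    prec = np.linalg.inv(target.cov)

    if model.A_sel is not None and model.vc_a is not None:
        prop = blup_posterior(model.y_sel, model.A_sel, model.vc_a)
    else:
        prop = target
    Lq = np.linalg.cholesky(prop.cov)

    # draw all proposals up front (independence sampler)
    Z = prop.mean + rng.standard_normal((n_iter, m)) @ Lq.T
    d = Z - target.mean
    quad_prop = np.einsum("ij,jk,ik->i", d, prec, d)
    corr_prop = log_correction(model, Z) if include_correction else np.zeros(n_iter)
    logq_prop = _mvn_chol_logpdf(Z, prop.mean, Lq)
    U = np.log(rng.uniform(size=n_iter))

    g_now = prop.mean.copy()
    d0 = g_now - target.mean
    quad_now = float(d0 @ prec @ d0)
    corr_now = float(log_correction(model, g_now)) if include_correction else 0.0
    logq_now = float(_mvn_chol_logpdf(g_now[None, :], prop.mean, Lq)[0])

    draws = np.empty((n_iter, m))
    accepted = 0
    accepted_burn = 0
    for i in range(n_iter):
        if mode == "full_mh":
            log_r = (-0.5 * (quad_prop[i] - quad_now)
                     + (corr_prop[i] - corr_now)
                     + (logq_now - logq_prop[i]))
        else:  # as_printed
            log_r = -0.5 * (quad_prop[i] - quad_now) + (corr_now - corr_prop[i])
        if U[i] <= log_r:
            g_now = Z[i]
            quad_now = quad_prop[i]
            corr_now = corr_prop[i]
            logq_now = logq_prop[i]
            accepted += 1
            if i < burn_in:
                accepted_burn += 1
        draws[i] = g_now
        if (i + 1) % LOG_BLOCK == 0:
            logger.info("preselect iter %d acceptance %.3f", i + 1,
                        accepted / (i + 1))

    if burn_in > 0 and accepted_burn / burn_in < 1e-3:
        logger.warning(
            "preselect sampler acceptance %.5f over burn-in; diagnostics: "
            "mode=%s t=%.3g proposal-mean-range=(%.3g, %.3g) "
            "target-mean-range=(%.3g, %.3g)",
            accepted_burn / burn_in, mode, model.t,
            prop.mean.min(), prop.mean.max(),
            target.mean.min(), target.mean.max(),
        )
    return MCMCChain(draws, accepted / n_iter, (seed,), ids=model.G_sel.ids)
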