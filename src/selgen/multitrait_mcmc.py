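"""Multi-trait sequential culling: Kronecker BLUP, orthant-probability
fitness, and a Metropolis sampler for the joint posterior.

Candidates are measured for traits 1..T-1 and culled unless every phenotype
exceeds its threshold; only survivors (the set S+) are measured for trait T
and presented to the analyst.  The multi-trait model is

    y = g + e,  g ~ N(0, G0 x G),  e ~ N(0, R0 x I)

(trait-major stacking; ``x`` the Kronecker product), with between-trait
genetic and residual covariances G0 and R0 and genomic relationship G.  The
posterior over all breeding values factors into the selection-ignoring
Gaussian for S+, the Gaussian of g_nsel given g_sel, and a culling term: for
each culled individual, the log-probability that its first T-1 phenotypes
all fell below the thresholds given its breeding values — a (T-1)-variate
normal lower-orthant probability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import multivariate_normal, norm

from .blup import BlupPosterior
from .cli_io import LOG_BLOCK, MCMCChain
from .core import MultiTraitCovariance, RelationshipMatrix

logger = logging.getLogger("selgen")

__all__ = [
    "CullingSpec",
    "MultiTraitModel",
    "multitrait_blup_sel",
    "culling_survival_prob",
    "conditional_nsel",
    "multitrait_log_posterior",
    "run_multitrait_sampler",
]

#: Fixed internal seed for the quasi-Monte-Carlo orthant probabilities, so
#: that repeated log-posterior evaluations are bit-identical (a requirement
#: for a deterministic Metropolis target).
_MVN_SEED = 20220701
_LOG_CLAMP = np.log(1e-300)


@dataclass
class CullingSpec:
    """Per-trait culling levels: observed in trait T only if every earlier
    phenotype strictly exceeded its threshold."""

    thresholds: np.ndarray

    def __post_init__(self) -> None:
        self.thresholds = np.atleast_1d(np.asarray(self.thresholds, dtype=float))
        if not np.all(np.isfinite(self.thresholds)):
            raise ValueError("culling thresholds must be finite")

    @property
    def n_stages(self) -> int:
        return len(self.thresholds)


@dataclass
class MultiTraitModel:
    """Kronecker-structured multi-trait model with a culled partition.

    cov0
        Between-trait covariances (G0, R0) of dimension T.
    K
        Relationship matrix over all candidates.
    sel_ids, nsel_ids
        The fully observed (S+) and culled (S-) individuals; together they
        must cover all ids in ``K``.
    Y_sel
        |S+| x T phenotype matrix of the survivors (centered).
    """

    cov0: MultiTraitCovariance
    K: RelationshipMatrix
    sel_ids: list
    nsel_ids: list
    Y_sel: np.ndarray

    def __post_init__(self) -> None:
        self.Y_sel = np.atleast_2d(np.asarray(self.Y_sel, dtype=float))
        if set(map(str, self.sel_ids)) | set(map(str, self.nsel_ids)) != set(
            map(str, self.K.ids)
        ):
            raise ValueError("sel_ids and nsel_ids must cover all ids in K")
        if self.Y_sel.shape != (len(self.sel_ids), self.cov0.n_traits):
            raise ValueError(
                f"Y_sel must be |S+| x T = {len(self.sel_ids)} x "
                f"{self.cov0.n_traits}, got {self.Y_sel.shape}"
            )

    @property
    def n_traits(self) -> int:
        return self.cov0.n_traits

    @property
    def n_sel(self) -> int:
        return len(self.sel_ids)

    @property
    def n_nsel(self) -> int:
        return len(self.nsel_ids)

    def G_blocks(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(G_sel,sel, G_nsel,sel, G_nsel,nsel) sub-blocks of K."""
        index = {str(v): i for i, v in enumerate(self.K.ids)}
        s = [index[str(i)] for i in self.sel_ids]
        u = [index[str(i)] for i in self.nsel_ids]
        K = self.K.K
        return K[np.ix_(s, s)], K[np.ix_(u, s)], K[np.ix_(u, u)]


def multitrait_blup_sel(model: MultiTraitModel) -> BlupPosterior:
    """Selection-ignoring posterior of the survivors' breeding values.

    mean = (G0 x Gs)(G0 x Gs + R0 x I)^-1 y,
    cov  = (G0 x Gs)[I - (G0 x Gs + R0 x I)^-1 (G0 x Gs)],

    stacked trait-major.  Computed through the eigendecomposition
    ``Gs = U D U'``, which turns the system into one T x T solve per
    eigencomponent; algebraically identical to the dense computation.
    """
    G0, R0 = model.cov0.G0, model.cov0.R0
    Gs, _, _ = model.G_blocks()
    T, ns = model.n_traits, model.n_sel
    d, U = np.linalg.eigh(Gs)
    Z = U.T @ model.Y_sel  # (ns, T): transformed phenotypes per eigencomponent

    A_k = np.empty((ns, T))       # transformed posterior mean coefficients
    B_k = np.empty((ns, T, T))    # transformed per-component posterior cov
    for k in range(ns):
        Gk = G0 * d[k]
        Mk = Gk + R0
        sol = np.linalg.solve(Mk, Z[k])
        A_k[k] = Gk @ sol
        B_k[k] = Gk - Gk @ np.linalg.solve(Mk, Gk)

    mean = (U @ A_k).T.reshape(T * ns)  # trait-major stack
    cov = np.empty((T * ns, T * ns))
    for i in range(T):
        for j in range(T):
            cov[i * ns:(i + 1) * ns, j * ns:(j + 1) * ns] = (
                U * B_k[:, i, j]
            ) @ U.T
    cov = (cov + cov.T) / 2
    return BlupPosterior(mean, cov)


def culling_survival_prob(
    g_i: np.ndarray,
    R0_sub: np.ndarray,
    thresholds: np.ndarray,
    abs_tol: float = 1e-6,
) -> float:
    """Probability that an individual was culled at every stage.

    ``Pr(y_1 < t_1, ..., y_{T-1} < t_{T-1} | g_i)`` — the lower-orthant
    probability of a normal with mean ``g_i`` (the individual's breeding
    values for the staged traits) and residual covariance ``R0_sub``.
    Computed by deterministic quasi-Monte-Carlo (fixed internal seed); an
    error is raised if the requested absolute tolerance is not reached.
    """
    g_i = np.atleast_1d(np.asarray(g_i, dtype=float))
    t = np.atleast_1d(np.asarray(thresholds, dtype=float))
    R0_sub = np.atleast_2d(np.asarray(R0_sub, dtype=float))
    k = len(t)
    if g_i.shape != (k,) or R0_sub.shape != (k, k):
        raise ValueError("g_i, R0_sub and thresholds must agree in dimension")
    if k == 1:
        return float(norm.cdf(t[0], loc=g_i[0], scale=np.sqrt(R0_sub[0, 0])))
    v1 = float(multivariate_normal.cdf(
        t, mean=g_i, cov=R0_sub, maxpts=2_000_000 * k, abseps=abs_tol / 10,
        releps=0.0, rng=np.random.default_rng(_MVN_SEED)))
    v2 = float(multivariate_normal.cdf(
        t, mean=g_i, cov=R0_sub, maxpts=500_000 * k, abseps=abs_tol / 10,
        releps=0.0, rng=np.random.default_rng(_MVN_SEED)))
    # the difference bounds the error of the cruder evaluation and is a
    # conservative estimate for the finer one that is returned
    err = abs(v1 - v2)
    if err > abs_tol:
        raise RuntimeError(
            f"orthant probability did not reach tolerance {abs_tol:g} "
            f"(achieved error estimate {err:.2e})"
        )
    return min(max(v1, 0.0), 1.0)


def conditional_nsel(
    g_sel: np.ndarray, model: MultiTraitModel
) -> tuple[np.ndarray, np.ndarray]:
    """Mean and covariance of the culled individuals' breeding values given
    the survivors': ``m = (I_T x G_ns G_ss^-1) g_sel``,
    ``V = G0 x (G_nn - G_ns G_ss^-1 G_sn)``."""
    Gs, Gns, Gnn = model.G_blocks()
    T, ns, nn = model.n_traits, model.n_sel, model.n_nsel
    g_sel = np.asarray(g_sel, dtype=float)
    if g_sel.shape != (T * ns,):
        raise ValueError("g_sel must be the trait-major stack over S+")
    B = np.linalg.solve(Gs.T, Gns.T).T  # G_ns G_ss^-1
    m = (B @ g_sel.reshape(T, ns).T).T.reshape(T * nn)
    schur = Gnn - B @ Gns.T
    V = np.kron(model.cov0.G0, (schur + schur.T) / 2)
    return m, V


class _MultitraitTarget:
    """Precomputed joint log-posterior over (g_sel stack, g_nsel stack).

    The Gaussian part is ``-0.5 g' H g + b' g``; the culling term adds, for
    each culled individual, the log lower-orthant probability of its staged
    traits (clamped at log(1e-300) to keep the target finite at extreme g).
    """

    def __init__(self, model: MultiTraitModel, culling: CullingSpec | None,
                 include_correction: bool = True):
        self.model = model
        self.culling = culling if include_correction else None
        T, ns, nn = model.n_traits, model.n_sel, model.n_nsel
        self.T, self.ns, self.nn = T, ns, nn
        if culling is not None and culling.n_stages != T - 1:
            raise ValueError("culling must have T-1 thresholds")

        post = multitrait_blup_sel(model)
        Ps = np.linalg.inv(post.cov)
        dim = T * (ns + nn)
        H = np.zeros((dim, dim))
        b = np.zeros(dim)
        if nn > 0:
            Gs, Gns, Gnn = model.G_blocks()
            B = np.linalg.solve(Gs.T, Gns.T).T
            A = np.kron(np.eye(T), B)                      # sel-stack -> m_{n|s}
            schur = Gnn - B @ Gns.T
            Pn = np.linalg.inv(np.kron(model.cov0.G0, (schur + schur.T) / 2))
            Pn = (Pn + Pn.T) / 2
            H[:T * ns, :T * ns] = Ps + A.T @ Pn @ A
            H[:T * ns, T * ns:] = -A.T @ Pn
            H[T * ns:, :T * ns] = -Pn @ A
            H[T * ns:, T * ns:] = Pn
        else:
            H[:, :] = Ps
        b[:T * ns] = Ps @ post.mean
        self.H = (H + H.T) / 2
        self.b = b
        self.blup = post
        self._R0_sub = model.cov0.R0[: T - 1, : T - 1] if T > 1 else None
        self._warned = False

    # -- culling term -------------------------------------------------------
    def log_cull_one(self, g_vec: np.ndarray, j: int) -> float:
        """Log culling probability of the j-th culled individual."""
        if self.culling is None:
            return 0.0
        T, ns, nn = self.T, self.ns, self.nn
        g_j = np.array([g_vec[T * ns + t * nn + j] for t in range(T - 1)])
        p = culling_survival_prob(g_j, self._R0_sub, self.culling.thresholds)
        if p <= 0 or np.log(max(p, 1e-320)) < _LOG_CLAMP:
            if not self._warned:
                logger.warning("culling probability underflow; clamped at log(1e-300)")
                self._warned = True
            return _LOG_CLAMP
        return float(np.log(p))

    def log_cull(self, g_vec: np.ndarray) -> float:
        return sum(self.log_cull_one(g_vec, j) for j in range(self.nn))

    def logpdf(self, g_vec: np.ndarray) -> float:
        g_vec = np.asarray(g_vec, dtype=float)
        quad = -0.5 * float(g_vec @ self.H @ g_vec) + float(self.b @ g_vec)
        return quad + self.log_cull(g_vec)

    def delta_quad(self, g_vec: np.ndarray, idx: np.ndarray,
                   new_vals: np.ndarray) -> float:
        """Change in the Gaussian part when entries ``idx`` become ``new_vals``."""
        dg = new_vals - g_vec[idx]
        Hrows = self.H[idx]
        lin = float((self.b[idx] - Hrows @ g_vec) @ dg)
        quad = -0.5 * float(dg @ Hrows[:, idx] @ dg)
        return lin + quad


def multitrait_log_posterior(
    g_all: np.ndarray,
    model: MultiTraitModel,
    culling: CullingSpec | None = None,
    include_correction: bool = True,
) -> float:
    """Joint log posterior (up to a constant) of the stacked vector
    ``(g_sel stack, g_nsel stack)``, trait-major within each partition."""
    target = _MultitraitTarget(model, culling, include_correction)
    g_all = np.asarray(g_all, dtype=float)
    if g_all.shape != (model.n_traits * (model.n_sel + model.n_nsel),):
        raise ValueError("g_all has the wrong dimension")
    return target.logpdf(g_all)


def _run_augmented_gibbs(
    model: MultiTraitModel,
    culling: CullingSpec | None,
    n_iter: int,
    seed: int,
    include_correction: bool = True,
) -> MCMCChain:
    """Data-augmentation Gibbs sampler for the culling-corrected posterior.

    The culling information is exactly "the staged phenotypes of each culled
    individual fell below their thresholds".  Augmenting the state with those
    latent phenotypes makes the model jointly Gaussian subject to box
    constraints on the latents: ``g | y_latent`` is one exact multivariate
    normal draw (precision Cholesky precomputed) and ``y_latent | g`` is a
    product of truncated normals over culled individuals (exact for a single
    staged trait; one inner Gibbs sweep over the staged traits otherwise).
    Marginally over the latents the chain targets exactly the same posterior
    as the Metropolis schemes, but it mixes in a few sweeps even when the
    relationship matrix makes single-coordinate moves degenerate.
    """
    from scipy.linalg import cho_factor, cho_solve, solve_triangular

    rng = np.random.default_rng(seed)
    T, ns, nn = model.n_traits, model.n_sel, model.n_nsel
    n = ns + nn
    dim = T * n
    G0, R0 = model.cov0.G0, model.cov0.R0
    Ts = T - 1  # staged traits
    use_latents = include_correction and culling is not None and nn > 0
    if culling is not None and culling.n_stages != Ts:
        raise ValueError("culling must have T-1 thresholds")

    # partitioned-stack index of (trait t, individual k in sel+nsel order)
    M = np.empty((T, n), dtype=int)
    for t in range(T):
        M[t, :ns] = t * ns + np.arange(ns)
        M[t, ns:] = T * ns + t * nn + np.arange(nn)

    index = {str(v): i for i, v in enumerate(model.K.ids)}
    order = [index[str(i)] for i in list(model.sel_ids) + list(model.nsel_ids)]
    Kperm = model.K.K[np.ix_(order, order)]
    P_kron = np.kron(np.linalg.inv(G0), np.linalg.inv(Kperm))
    pos = M.reshape(-1)  # kron index -> partitioned index
    H = np.zeros((dim, dim))
    H[np.ix_(pos, pos)] = P_kron
    b0 = np.zeros(dim)
    R0inv = np.linalg.inv(R0)
    for i in range(ns):
        idx = M[:, i]
        H[np.ix_(idx, idx)] += R0inv
        b0[idx] += R0inv @ model.Y_sel[i]
    if use_latents:
        Rsub = R0[:Ts, :Ts]
        Rsubinv = np.linalg.inv(Rsub)
        staged = np.stack([M[t, ns:] for t in range(Ts)], axis=1)  # (nn, Ts)
        for j in range(nn):
            H[np.ix_(staged[j], staged[j])] += Rsubinv
        t_vec = culling.thresholds
        # start the latents just inside the truncation region
        y_lat = np.minimum(np.zeros((nn, Ts)), t_vec - 0.5)
    H = (H + H.T) / 2
    c, low = cho_factor(H, lower=True)
    L = np.tril(c)

    draws = np.empty((n_iter, dim))
    for it in range(n_iter):
        b = b0.copy()
        if use_latents:
            contrib = y_lat @ Rsubinv.T
            np.add.at(b, staged.reshape(-1), contrib.reshape(-1))
        mean = cho_solve((c, low), b)
        g = mean + solve_triangular(L.T, rng.standard_normal(dim), lower=False)
        if use_latents:
            g_staged = g[staged]  # (nn, Ts)
            if Ts == 1:
                sd = np.sqrt(Rsub[0, 0])
                tail = norm.cdf((t_vec[0] - g_staged[:, 0]) / sd)
                tail = np.clip(tail, 1e-300, 1.0)
                u = rng.uniform(size=nn)
                y_lat[:, 0] = g_staged[:, 0] + sd * norm.ppf(
                    np.clip(u * tail, 1e-300, 1 - 1e-16))
            else:
                # one Gibbs sweep over the staged traits of each latent
                for s in range(Ts):
                    others = [a for a in range(Ts) if a != s]
                    beta = np.linalg.solve(Rsub[np.ix_(others, others)],
                                           Rsub[others, s])
                    cv = Rsub[s, s] - Rsub[s, others] @ beta
                    cm = (g_staged[:, s]
                          + (y_lat[:, others] - g_staged[:, others]) @ beta)
                    sd = np.sqrt(cv)
                    tail = np.clip(norm.cdf((t_vec[s] - cm) / sd), 1e-300, 1.0)
                    u = rng.uniform(size=nn)
                    y_lat[:, s] = cm + sd * norm.ppf(
                        np.clip(u * tail, 1e-300, 1 - 1e-16))
        draws[it] = g
        if (it + 1) % LOG_BLOCK == 0:
            logger.info("multitrait augmented-gibbs iter %d", it + 1)

    ids = ([f"t{t}:{i}" for t in range(T) for i in model.sel_ids]
           + [f"t{t}:{i}" for t in range(T) for i in model.nsel_ids])
    return MCMCChain(draws, 1.0, (seed,), ids=ids)


def _proposal_moments(
    model: MultiTraitModel,
    overdispersion: float,
    proposal_K: RelationshipMatrix | None = None,
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Per-trait independence-proposal mean and covariance over all
    individuals (ordering: sel then nsel within each trait).

    mean_t = G_tt K (G_tt K + c R_tt I)^-1 y_t  (missing phenotypes as 0),
    cov_t  = G_tt K [I - (G_tt K + c R_tt I)^-1 G_tt K].
    """
    Kmat = (proposal_K or model.K).K
    index = {str(v): i for i, v in enumerate(model.K.ids)}
    order = [index[str(i)] for i in list(model.sel_ids) + list(model.nsel_ids)]
    Kmat = Kmat[np.ix_(order, order)]
    n = Kmat.shape[0]
    T, ns = model.n_traits, model.n_sel
    G0, R0 = model.cov0.G0, model.cov0.R0
    c = overdispersion
    means = np.empty((T, n))
    covs = []
    for t in range(T):
        y_t = np.zeros(n)
        y_t[:ns] = model.Y_sel[:, t]
        GK = G0[t, t] * Kmat
        M = np.linalg.solve((GK + c * R0[t, t] * np.eye(n)).T, GK.T).T
        means[t] = M @ y_t
        C = GK - M @ GK
        covs.append((C + C.T) / 2)
    return means, covs


def run_multitrait_sampler(
    model: MultiTraitModel,
    culling: CullingSpec | None,
    n_iter: int = 5000,
    seed: int = 0,
    overdispersion: float = 2.0,
    mode: str = "full_mh",
    block: str = "full",
    include_correction: bool = True,
    proposal_K: RelationshipMatrix | None = None,
) -> MCMCChain:
    """Metropolis sampler for the joint culling-corrected posterior.

    The proposal is the per-trait single-trait BLUP posterior with residual
    variance inflated by ``overdispersion`` (default 2), blocks independent
    across traits; ``proposal_K`` substitutes a different relationship
    matrix in the proposal only (the target is untouched).  ``block``
    chooses the update granularity:

    ``full``
        whole-vector independence Metropolis;
    ``per_trait``
        one independence update per trait block per sweep;
    ``per_individual``
        one update per individual per sweep (all its traits jointly),
        proposing from the individual's exact Gaussian full conditional so
        that only the culling term enters the acceptance ratio
        (Metropolis-within-Gibbs); mixes slowly when the relationship
        matrix couples individuals strongly;
    ``augmented``
        data-augmentation Gibbs (see :func:`_run_augmented_gibbs`): the
        culled individuals' staged phenotypes are kept as truncated-normal
        latent variables and the whole breeding-value vector is redrawn
        jointly each sweep — the practical choice beyond a few dozen
        individuals, where the other schemes move essentially not at all
        because relatives pin each breeding value down far more tightly
        than its marginal.

    ``mode="full_mh"`` includes the independence-proposal Hastings factor;
    ``"as_printed"`` omits it.  Draw layout matches
    :func:`multitrait_log_posterior` (trait-major; S+ then S- in each trait).
    """
    if mode not in ("full_mh", "as_printed"):
        raise ValueError(f"unknown mode {mode!r}")
    if block not in ("full", "per_trait", "per_individual", "augmented"):
        raise ValueError(f"unknown block scheme {block!r}")
    if block == "augmented":
        return _run_augmented_gibbs(model, culling, n_iter, seed,
                                    include_correction)
    rng = np.random.default_rng(seed)
    T, ns, nn = model.n_traits, model.n_sel, model.n_nsel
    n = ns + nn
    dim = T * n
    target = _MultitraitTarget(model, culling, include_correction)
    means, covs = _proposal_moments(model, overdispersion, proposal_K)
    chols = [np.linalg.cholesky(C + 1e-10 * np.trace(C) / n * np.eye(n))
             for C in covs]

    from scipy.linalg import solve_triangular

    # map (trait t, individual j in sel+nsel order) -> partitioned stack index
    M = np.empty((T, n), dtype=int)
    for t in range(T):
        M[t, :ns] = t * ns + np.arange(ns)
        M[t, ns:] = T * ns + t * nn + np.arange(nn)

    def q_logpdf_trait(t: int, x: np.ndarray) -> float:
        w = solve_triangular(chols[t], x - means[t], lower=True)
        return -0.5 * float(w @ w) - float(np.sum(np.log(np.diag(chols[t]))))

    g = np.empty(dim)
    for t in range(T):
        g[M[t]] = means[t]
    draws = np.empty((n_iter, dim))
    n_acc = 0
    n_try = 0

    if block == "full":
        lp_now = target.logpdf(g)
        lq_now = sum(q_logpdf_trait(t, g[M[t]]) for t in range(T))
        for i in range(n_iter):
            prop = np.empty(dim)
            for t in range(T):
                prop[M[t]] = means[t] + chols[t] @ rng.standard_normal(n)
            lp_prop = target.logpdf(prop)
            lq_prop = sum(q_logpdf_trait(t, prop[M[t]]) for t in range(T))
            log_r = lp_prop - lp_now
            if mode == "full_mh":
                log_r += lq_now - lq_prop
            n_try += 1
            if np.log(rng.uniform()) <= log_r:
                g, lp_now, lq_now = prop, lp_prop, lq_prop
                n_acc += 1
            draws[i] = g
            if (i + 1) % LOG_BLOCK == 0:
                logger.info("multitrait iter %d acceptance %.3f", i + 1,
                            n_acc / n_try)

    elif block == "per_trait":
        for i in range(n_iter):
            for t in range(T):
                idx = M[t]
                prop_t = means[t] + chols[t] @ rng.standard_normal(n)
                g_prop = g.copy()
                g_prop[idx] = prop_t
                log_r = (target.delta_quad(g, idx, prop_t)
                         + target.log_cull(g_prop) - target.log_cull(g))
                if mode == "full_mh":
                    log_r += q_logpdf_trait(t, g[idx]) - q_logpdf_trait(t, prop_t)
                n_try += 1
                if np.log(rng.uniform()) <= log_r:
                    g = g_prop
                    n_acc += 1
            draws[i] = g

    else:  # per_individual
        # Metropolis-within-Gibbs: propose each individual's T-vector from
        # its exact Gaussian full conditional (so the Gaussian part of the
        # acceptance ratio cancels) and accept with the culling-term ratio
        # alone; survivors are accepted with probability 1.
        H, b = target.H, target.b
        Hbb = [H[np.ix_(M[:, j], M[:, j])] for j in range(n)]
        Lbb = [np.linalg.cholesky(Hb) for Hb in Hbb]
        noise = rng.standard_normal((n_iter, n, T))
        logu = np.log(rng.uniform(size=(n_iter, n)))
        cull_now = np.array(
            [target.log_cull_one(g, j) for j in range(nn)]
        ) if (target.culling is not None and nn) else np.zeros(0)
        for i in range(n_iter):
            for j in range(n):
                idx = M[:, j]
                r_vec = b[idx] - H[idx] @ g + Hbb[j] @ g[idx]
                cond_mean = np.linalg.solve(Hbb[j], r_vec)
                # sample from N(cond_mean, Hbb^-1) via L'^-1 z
                prop_j = cond_mean + solve_triangular(
                    Lbb[j].T, noise[i, j], lower=False)
                if target.culling is not None and j >= ns:
                    g_prop = g.copy()
                    g_prop[idx] = prop_j
                    cull_prop = target.log_cull_one(g_prop, j - ns)
                    log_r = cull_prop - cull_now[j - ns]
                    n_try += 1
                    if logu[i, j] <= log_r:
                        g[idx] = prop_j
                        cull_now[j - ns] = cull_prop
                        n_acc += 1
                else:
                    n_try += 1
                    n_acc += 1
                    g[idx] = prop_j
            draws[i] = g

    ids = ([f"t{t}:{i}" for t in range(T) for i in model.sel_ids]
           + [f"t{t}:{i}" for t in range(T) for i in model.nsel_ids])
    return MCMCChain(draws, n_acc / max(n_try, 1), (seed,), ids=ids)
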