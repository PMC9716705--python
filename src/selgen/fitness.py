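"""Fitness functions, Bayesian mean fitness and numeric ignorability checks.

Selection is encoded by a fitness function ``H(y | phi)`` giving the
probability (up to scale) that an individual with phenotypes ``y`` survives,
i.e. that its records are observed.  Multiplying the likelihood by the
expected fitness yields the posterior under selection; when fitness depends
only on observed data and its parameters are a priori independent of the
model parameters, the posterior is unchanged and selection is *ignorable*.

All posterior arithmetic is done on a one-dimensional parameter grid in log
space: the correction terms are sums of log normal tails which underflow in
linear space.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.special import logsumexp
from scipy.stats import norm

__all__ = [
    "FitnessSpec",
    "GridPosteriorProblem",
    "PosteriorGrid",
    "evaluate_fitness",
    "mean_fitness",
    "posterior_under_selection",
    "check_ignorability",
    "default_grid",
]

_KINDS = ("truncation_above", "truncation_below", "nor_optimal", "constant")

#: Default grid: centre +/- 8 sd with this many points.  Wide enough to cover
#: selection-shifted posterior mass; cheap for trapezoid quadrature.
GRID_POINTS = 2001
GRID_HALF_WIDTH_SD = 8.0


@dataclass
class FitnessSpec:
    """A selection rule.

    kind
        ``truncation_above`` (survive iff ``y > t``, strict), ``truncation_below``
        (survive iff ``y < t``), ``nor_optimal`` (Gaussian fitness
        ``exp(-0.5 (y-lambda)' Gamma^-1 (y-lambda))`` peaked at the optimum
        ``lambda`` with sharpness ``Gamma``), or ``constant`` (no selection).
    t
        Threshold(s), trait units, for the truncation kinds.
    lambda_opt, Gamma
        Optimum vector and sharpness matrix (trait-units^2) for ``nor_optimal``.
    """

    kind: str
    t: float | np.ndarray | None = None
    lambda_opt: np.ndarray | None = None
    Gamma: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown fitness kind {self.kind!r}")
        if self.kind in ("truncation_above", "truncation_below"):
            if self.t is None:
                raise ValueError(f"{self.kind} requires a threshold t")
            self.t = np.atleast_1d(np.asarray(self.t, dtype=float))
            if np.any(np.isnan(self.t)):
                raise ValueError("thresholds must be finite or +/- inf")
        elif self.kind == "nor_optimal":
            if self.lambda_opt is None or self.Gamma is None:
                raise ValueError("nor_optimal requires lambda_opt and Gamma")
            self.lambda_opt = np.atleast_1d(np.asarray(self.lambda_opt, dtype=float))
            self.Gamma = np.atleast_2d(np.asarray(self.Gamma, dtype=float))
            if not np.allclose(self.Gamma, self.Gamma.T):
                raise ValueError("Gamma must be symmetric")
            if np.any(np.linalg.eigvalsh(self.Gamma) <= 0):
                raise ValueError("Gamma must be positive definite")

    @property
    def dim(self) -> int:
        if self.kind in ("truncation_above", "truncation_below"):
            return len(self.t)
        if self.kind == "nor_optimal":
            return len(self.lambda_opt)
        return 1

    # -- JSON round trip ----------------------------------------------------
    def to_dict(self) -> dict:
        d: dict = {"kind": self.kind}
        if self.t is not None:
            d["t"] = np.asarray(self.t).tolist()
        if self.lambda_opt is not None:
            d["lambda_opt"] = np.asarray(self.lambda_opt).tolist()
        if self.Gamma is not None:
            d["Gamma"] = np.asarray(self.Gamma).tolist()
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_dict(cls, d: dict) -> "FitnessSpec":
        return cls(
            kind=d["kind"],
            t=d.get("t"),
            lambda_opt=d.get("lambda_opt"),
            Gamma=d.get("Gamma"),
        )

    @classmethod
    def from_json(cls, s: str) -> "FitnessSpec":
        return cls.from_dict(json.loads(s))

    def to_yaml(self) -> str:
        import yaml

        return yaml.safe_dump(self.to_dict())

    @classmethod
    def from_yaml(cls, s: str) -> "FitnessSpec":
        import yaml

        return cls.from_dict(yaml.safe_load(s))


def evaluate_fitness(spec: FitnessSpec, y: np.ndarray | float) -> float:
    """Fitness of phenotype ``y`` under ``spec``; a value in [0, 1].

    Truncation uses the strict-inequality convention (``y == t`` does not
    survive "above" selection); a measure-zero event for continuous traits,
    fixed here for reproducibility.
    """
    y = np.atleast_1d(np.asarray(y, dtype=float))
    if spec.kind == "constant":
        return 1.0
    if len(y) != spec.dim:
        raise ValueError(f"phenotype dimension {len(y)} != spec dimension {spec.dim}")
    if spec.kind == "truncation_above":
        return float(np.all(y > spec.t))
    if spec.kind == "truncation_below":
        return float(np.all(y < spec.t))
    # nor-optimal Gaussian fitness, maximal (1) at the optimum
    d = y - spec.lambda_opt
    q = d @ np.linalg.solve(spec.Gamma, d)
    return float(np.exp(-0.5 * q))


def mean_fitness(spec: FitnessSpec, grid: np.ndarray, density: np.ndarray) -> float:
    """Bayesian mean fitness ``H-bar``: the integral of fitness x density.

    ``density`` is a data-generating density tabulated on ``grid`` (must
    integrate to 1 within 1e-6).  For truncation selection on a normal
    density this equals the corresponding tail probability up to quadrature
    error.  Selection that removes all probability mass is degenerate.
    """
    grid = np.asarray(grid, dtype=float)
    density = np.asarray(density, dtype=float)
    total = np.trapezoid(density, grid)
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"density integrates to {total:.8f}, not 1")
    if spec.kind in ("truncation_above", "truncation_below") and spec.dim == 1:
        # split the integration cell exactly at the threshold: multiplying
        # the indicator on grid nodes leaves an O(dx) error at the jump
        t = float(spec.t[0])
        if grid[0] < t < grid[-1]:
            dens_t = float(np.interp(t, grid, density))
            keep = grid > t if spec.kind == "truncation_above" else grid < t
            if spec.kind == "truncation_above":
                sub_g = np.concatenate([[t], grid[keep]])
                sub_d = np.concatenate([[dens_t], density[keep]])
            else:
                sub_g = np.concatenate([grid[keep], [t]])
                sub_d = np.concatenate([density[keep], [dens_t]])
            hbar = float(np.trapezoid(sub_d, sub_g))
        elif (t <= grid[0]) == (spec.kind == "truncation_above"):
            hbar = float(total)
        else:
            hbar = 0.0
    else:
        h = np.array([evaluate_fitness(spec, v) for v in grid])
        hbar = float(np.trapezoid(h * density, grid))
    if hbar <= 0:
        raise ValueError("degenerate selection: mean fitness is zero")
    return hbar


@dataclass
class GridPosteriorProblem:
    """A scalar-parameter posterior assembled on a grid.

    ``log_lik``, ``log_prior`` and ``log_fitness_correction`` are callables
    of the scalar parameter (vectorized over the grid).  The correction is
    the log of the expected-fitness factor that multiplies the likelihood
    under selection; identically zero means no selection.
    """

    param_name: str
    grid: np.ndarray
    log_lik: Callable[[np.ndarray], np.ndarray]
    log_prior: Callable[[np.ndarray], np.ndarray] = lambda g: np.zeros_like(g)
    log_fitness_correction: Callable[[np.ndarray], np.ndarray] = (
        lambda g: np.zeros_like(g)
    )

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if len(self.grid) < 101:
            raise ValueError("grid must have at least 101 points")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")

    def log_terms(self) -> np.ndarray:
        g = self.grid
        out = (
            np.asarray(self.log_lik(g), dtype=float)
            + np.asarray(self.log_prior(g), dtype=float)
            + np.asarray(self.log_fitness_correction(g), dtype=float)
        )
        if np.any(np.isnan(out)) or np.any(out == np.inf):
            raise ValueError("log-density terms must be finite or -inf")
        return out


@dataclass
class PosteriorGrid:
    """A normalized posterior density tabulated on a grid."""

    grid: np.ndarray
    density: np.ndarray
    mean: float = field(init=False)
    mode: float = field(init=False)
    sd: float = field(init=False)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if np.any(self.density < 0):
            raise ValueError("density must be non-negative")
        total = np.trapezoid(self.density, self.grid)
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"density integrates to {total:.10f}, not 1")
        self.mean = float(np.trapezoid(self.grid * self.density, self.grid))
        m2 = float(np.trapezoid(self.grid**2 * self.density, self.grid))
        self.sd = float(np.sqrt(max(m2 - self.mean**2, 0.0)))
        self.mode = float(self.grid[np.argmax(self.density)])

    def cdf(self) -> np.ndarray:
        """Cumulative distribution by trapezoid accumulation."""
        dx = np.diff(self.grid)
        c = np.concatenate(
            [[0.0], np.cumsum(0.5 * dx * (self.density[1:] + self.density[:-1]))]
        )
        return c / c[-1]

    def credible_interval(self, alpha: float = 0.05) -> tuple[float, float]:
        """Equal-tail (1 - alpha) credible interval by inverse CDF."""
        c = self.cdf()
        lo = float(np.interp(alpha / 2, c, self.grid))
        hi = float(np.interp(1 - alpha / 2, c, self.grid))
        return lo, hi


def default_grid(center: float, sd: float, n: int = GRID_POINTS,
                 half_width: float = GRID_HALF_WIDTH_SD) -> np.ndarray:
    """Grid centred on the unselected posterior mean, +/- ``half_width`` sd."""
    return np.linspace(center - half_width * sd, center + half_width * sd, n)


def posterior_under_selection(problem: GridPosteriorProblem) -> PosteriorGrid:
    """Normalize ``exp(log_lik + log_prior + log_fitness_correction)``.

    Normalization is by log-sum-exp followed by trapezoid quadrature; with a
    correction identically zero this is the no-selection posterior.  Adding a
    constant to any log term leaves the result unchanged.
    """
    logp = problem.log_terms()
    if np.all(np.isneginf(logp)):
        raise ValueError("posterior has no support on grid")
    logp = logp - logsumexp(logp)
    dens = np.exp(logp)
    dens /= np.trapezoid(dens, problem.grid)
    return PosteriorGrid(problem.grid, dens)


def check_ignorability(
    problem_with_fitness: GridPosteriorProblem,
    problem_without_fitness: GridPosteriorProblem,
) -> float:
    """Sup-norm distance between the two normalized grid posteriors.

    Near zero means the selection mechanism is ignorable for this parameter.
    """
    if (problem_with_fitness.grid.shape != problem_without_fitness.grid.shape
            or not np.allclose(problem_with_fitness.grid,
                               problem_without_fitness.grid)):
        raise ValueError("problems must share an identical grid")
    a = posterior_under_selection(problem_with_fitness)
    b = posterior_under_selection(problem_without_fitness)
    return float(np.max(np.abs(a.density - b.density)))


def log_marginal_likelihood(problem: GridPosteriorProblem) -> float:
    """Log of the grid integral of lik x prior x fitness-correction.

    Used by the model-probability invariance check: an observed-data-only
    fitness factor with fixed parameters multiplies every model's marginal
    likelihood by the same constant, leaving posterior model probabilities
    unchanged.
    """
    logp = problem.log_terms()
    # trapezoid weights in log space
    dx = np.diff(problem.grid)
    w = np.concatenate([[dx[0] / 2], (dx[1:] + dx[:-1]) / 2, [dx[-1] / 2]])
    return float(logsumexp(logp + np.log(w)))


def posterior_model_probabilities(
    problems: list[GridPosteriorProblem], prior_probs: np.ndarray | None = None
) -> np.ndarray:
    """Posterior probabilities of competing models from grid marginals."""
    logm = np.array([log_marginal_likelihood(p) for p in problems])
    if prior_probs is None:
        prior_probs = np.full(len(problems), 1.0 / len(problems))
    logw = logm + np.log(np.asarray(prior_probs, dtype=float))
    return np.exp(logw - logsumexp(logw))
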