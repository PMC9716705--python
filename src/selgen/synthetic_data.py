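"""Seeded generators for every data structure the selection pipelines consume.

Each generator is a pure function of its arguments and the seed
(bit-reproducible) and emulates one of the study designs: correlated-trait
truncation across two countries, an inbred-line genomic population with
binary markers, a forward-simulated pedigree population, and
Kronecker-covariance multi-trait phenotypes with sequential culling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    MissingnessPattern,
    RelationshipMatrix,
    genomic_relationship,
    nearest_psd,
    pedigree_relationship,
)

__all__ = [
    "SimulationConfig",
    "simulate_bivariate_selection",
    "simulate_genomic_population",
    "simulate_pedigree_population",
    "simulate_multitrait",
    "apply_sequential_culling",
]


@dataclass
class SimulationConfig:
    """Bundle of generator settings used by the CLI presets."""

    seed: int
    n_individuals: int = 1000
    n_markers: int = 1000
    maf_range: tuple[float, float] = (0.05, 0.5)
    rho: float = 0.8
    thresholds: tuple[float, ...] = (0.0,)
    G0: np.ndarray | None = None
    R0: np.ndarray | None = None
    sigma2_g: float = 0.5
    sigma2_e: float = 0.5
    protocol: str = "example1"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for v in (self.sigma2_g, self.sigma2_e):
            if v < 0:
                raise ValueError("variances must be >= 0")


def simulate_bivariate_selection(
    n: int,
    rho: float,
    mu_A: float = 0.0,
    mu_B: float = 0.0,
    threshold: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, MissingnessPattern, np.ndarray]:
    """Correlated-trait truncation: trait B observed only when trait A > t.

    Draws ``n`` iid pairs from a bivariate normal with unit variances and
    correlation ``rho``; the returned missingness pattern marks trait B
    observed iff trait A strictly exceeded the threshold, and trait A as
    never observed (its records are withheld from the analyst).

    Returns ``(complete pairs (n, 2), pattern (n, 2), observed trait-B records)``.
    """
    if not abs(rho) < 1:
        raise ValueError("|rho| must be < 1")
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(np.array([[1.0, rho], [rho, 1.0]]))
    pairs = np.array([mu_A, mu_B]) + rng.standard_normal((n, 2)) @ L.T
    sel = pairs[:, 0] > threshold
    r = np.zeros((n, 2), dtype=int)
    r[:, 1] = sel.astype(int)
    if not sel.any():  # keep the pattern valid even under absurd thresholds
        raise ValueError("selection removed every record")
    return pairs, MissingnessPattern(r), pairs[sel, 1].copy()


def simulate_genomic_population(
    n: int,
    p: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    sigma2_g: float = 0.5,
    sigma2_e: float = 0.5,
    seed: int = 0,
    diploid: bool = False,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Inbred-line genomic population with binary presence/absence markers.

    Per-locus allele frequencies are drawn uniformly in ``maf_range``.
    Fully homozygous lines give 0/1 codes (``diploid=True`` gives 0/1/2
    counts instead).  Breeding values are ``g = Z beta`` with
    ``beta ~ N(0, sigma2_g / p)`` on the centered-and-standardized marker
    matrix ``Z`` — the equivalent-effects model behind ``G = XX'/p`` — so the
    genetic variance across individuals is close to ``sigma2_g``.
    Phenotypes are ``y = g + e`` with ``e ~ N(0, sigma2_e)``.

    Returns ``(marker DataFrame, true g, phenotypes)``.
    """
    if p < 2:
        raise ValueError("need at least 2 markers")
    rng = np.random.default_rng(seed)
    freq = rng.uniform(*maf_range, size=p)
    if diploid:
        X = rng.binomial(2, freq, size=(n, p)).astype(float)
    else:
        X = (rng.uniform(size=(n, p)) < freq).astype(float)
    Xc = X - X.mean(axis=0)
    sd = X.std(axis=0)
    keep = sd > 0
    Z = np.zeros_like(Xc)
    Z[:, keep] = Xc[:, keep] / sd[keep]
    beta = rng.normal(0.0, np.sqrt(sigma2_g / keep.sum()), size=p) * keep
    g = Z @ beta
    y = g + rng.normal(0.0, np.sqrt(sigma2_e), size=n)
    ids = [f"L{i:04d}" for i in range(n)]
    cols = [f"M{j:04d}" for j in range(p)]
    return pd.DataFrame(X, index=pd.Index(ids, name="id"), columns=cols), g, y


def simulate_pedigree_population(
    founders: int,
    generations: int,
    offspring_per_mating: int,
    h2: float,
    seed: int = 0,
    sigma2_p: float = 1.0,
) -> tuple[list[tuple], RelationshipMatrix, np.ndarray, np.ndarray]:
    """Random-mating forward simulation with additive breeding values.

    Founders get independent ``N(0, sigma2_a)`` breeding values; each
    offspring receives the parent average plus a Mendelian-sampling deviate
    of variance ``sigma2_a (1/2 - (F_s + F_d)/4)``, so that jointly
    ``a ~ N(0, A sigma2_a)``.  Phenotypes are ``y = a + e`` with
    ``sigma2_a = h2 sigma2_p`` and ``sigma2_e = (1 - h2) sigma2_p``.

    Returns ``(pedigree triples, A, true a, phenotypes)``.
    """
    if founders < 2:
        raise ValueError("need at least 2 founders")
    if not 0 < h2 < 1:
        raise ValueError("h2 must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    sigma2_a = h2 * sigma2_p

    pedigree: list[tuple] = [(f"F{i:03d}", None, None) for i in range(founders)]
    prev_gen = [t[0] for t in pedigree]
    for gen in range(1, generations + 1):
        new_gen = []
        n_matings = max(len(prev_gen) // 2, 1)
        for m in range(n_matings):
            sire, dam = rng.choice(prev_gen, size=2, replace=False)
            for k in range(offspring_per_mating):
                cid = f"G{gen}_{m:03d}_{k}"
                pedigree.append((cid, sire, dam))
                new_gen.append(cid)
        prev_gen = new_gen
    A = pedigree_relationship(pedigree)
    index = {v: i for i, v in enumerate(A.ids)}

    a = np.zeros(A.n)
    for iid, sire, dam in pedigree:
        i = index[iid]
        if sire is None and dam is None:
            a[i] = rng.normal(0.0, np.sqrt(sigma2_a))
        else:
            s, d = index[sire], index[dam]
            F_s, F_d = A.K[s, s] - 1.0, A.K[d, d] - 1.0
            mend_var = sigma2_a * (0.5 - (F_s + F_d) / 4.0)
            a[i] = 0.5 * (a[s] + a[d]) + rng.normal(0.0, np.sqrt(mend_var))
    y = a + rng.normal(0.0, np.sqrt((1 - h2) * sigma2_p), size=A.n)
    return pedigree, A, a, y


def simulate_multitrait(
    G0: np.ndarray,
    R0: np.ndarray,
    K: RelationshipMatrix,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Multi-trait phenotypes with ``g ~ N(0, G0 x K)``, ``e ~ N(0, R0 x I)``.

    Returns ``(Y (n x T), true breeding values (n x T))``.  Non-PSD inputs
    are repaired with a warning.
    """
    import warnings

    rng = np.random.default_rng(seed)
    G0 = np.atleast_2d(np.asarray(G0, dtype=float))
    R0 = np.atleast_2d(np.asarray(R0, dtype=float))
    T = G0.shape[0]
    n = K.n

    def _chol(Mat, name):
        w = np.linalg.eigvalsh((Mat + Mat.T) / 2)
        if w[0] < 0:
            warnings.warn(f"{name} is not PSD; repairing", stacklevel=2)
            Mat = nearest_psd(Mat)
        return np.linalg.cholesky(Mat + 1e-12 * np.eye(Mat.shape[0]))

    L0 = _chol(G0, "G0")
    Lk = _chol(K.K, "K")
    Lr = _chol(R0, "R0")
    # chol(G0 x K) = chol(G0) x chol(K): draw the trait-major stack
    Zg = rng.standard_normal((T, n))
    Gmat = (L0 @ Zg @ Lk.T).T  # (n, T)
    E = rng.standard_normal((n, T)) @ Lr.T
    return Gmat + E, Gmat


def apply_sequential_culling(
    Y: np.ndarray, thresholds: Sequence[float]
) -> tuple[np.ndarray, np.ndarray, MissingnessPattern]:
    """Partition individuals by the sequential culling rule.

    An individual joins S+ iff its phenotype strictly exceeds the threshold
    for every one of the first T-1 traits; otherwise the final trait is
    masked.  Returns ``(S+ row indices, S- row indices, pattern (n, T))``.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    t = np.asarray(thresholds, dtype=float)
    n, T = Y.shape
    if len(t) != T - 1:
        raise ValueError(f"need T-1 = {T - 1} thresholds, got {len(t)}")
    sel = np.all(Y[:, : T - 1] > t, axis=1)
    r = np.ones((n, T), dtype=int)
    r[~sel, T - 1] = 0
    return np.where(sel)[0], np.where(~sel)[0], MissingnessPattern(r)
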