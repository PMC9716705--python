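"""Shared domain types for quantitative-genetic models under selection.

Relationship matrices (pedigree ``A`` or genomic ``G``), variance components,
multi-trait covariance structures and missingness patterns.  A relationship
matrix is the covariance structure (up to a variance component) among breeding
values: ``A`` is derived from a pedigree by the tabular method, and
``G = XX'/p`` from a centered and standardized marker matrix ``X`` with ``p``
markers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RelationshipMatrix",
    "VarianceComponents",
    "MultiTraitCovariance",
    "MissingnessPattern",
    "genomic_relationship",
    "pedigree_relationship",
    "nearest_psd",
]

#: Default relative eigenvalue floor used by PSD repair.  Small enough not to
#: visibly distort a covariance matrix, large enough that the repaired matrix
#: is numerically invertible.
PSD_FLOOR = 1e-8

_SYM_TOL = 1e-10


@dataclass
class RelationshipMatrix:
    """Symmetric PSD matrix of relatedness coefficients with individual ids.

    Parameters
    ----------
    ids
        Individual identifiers, one per row/column of ``K``.
    K
        Square symmetric matrix of relatedness coefficients (unitless).
    kind
        One of ``{"pedigree", "genomic", "identity"}``.
    """

    ids: list
    K: np.ndarray
    kind: str = "genomic"

    def __post_init__(self) -> None:
        self.K = np.asarray(self.K, dtype=float)
        self.ids = list(self.ids)
        n = len(self.ids)
        if self.K.shape != (n, n):
            raise ValueError(
                f"K must be {n}x{n} to match ids, got {self.K.shape}"
            )
        if self.kind not in ("pedigree", "genomic", "identity"):
            raise ValueError(f"unknown relationship kind {self.kind!r}")
        if not np.allclose(self.K, self.K.T, atol=_SYM_TOL):
            raise ValueError("relationship matrix is not symmetric")
        w = np.linalg.eigvalsh(self.K)
        if w.size and w[0] < -1e-8 * max(w[-1], 1.0):
            raise ValueError(
                "relationship matrix has a large negative eigenvalue "
                f"({w[0]:.3e}); repair it with nearest_psd first"
            )
        if self.kind == "pedigree" and np.any(np.diag(self.K) < 1 - 1e-10):
            raise ValueError("pedigree relationship diagonal must be >= 1")

    @property
    def n(self) -> int:
        return len(self.ids)

    def repaired(self, floor: float = PSD_FLOOR) -> "RelationshipMatrix":
        """Return a copy whose matrix has been floored to PSD."""
        return RelationshipMatrix(self.ids, nearest_psd(self.K, floor), self.kind)

    def submatrix(self, ids: Sequence) -> "RelationshipMatrix":
        """Restrict to a subset of individuals (in the given order)."""
        index = {v: i for i, v in enumerate(self.ids)}
        rows = [index[i] for i in ids]
        return RelationshipMatrix(list(ids), self.K[np.ix_(rows, rows)], self.kind)

    @classmethod
    def identity(cls, ids: Sequence) -> "RelationshipMatrix":
        return cls(list(ids), np.eye(len(ids)), "identity")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.K, index=self.ids, columns=self.ids)


@dataclass
class VarianceComponents:
    """Genetic and residual variance of a single-trait random-effects model.

    ``y = u + e`` with ``u ~ N(0, K sigma2_u)`` and ``e ~ N(0, I sigma2_e)``.
    Heritability is the derived ratio ``h2 = sigma2_u / (sigma2_u + sigma2_e)``.
    """

    sigma2_u: float
    sigma2_e: float

    def __post_init__(self) -> None:
        if self.sigma2_u <= 0 or self.sigma2_e <= 0:
            raise ValueError("variance components must be > 0")

    @property
    def h2(self) -> float:
        return self.sigma2_u / (self.sigma2_u + self.sigma2_e)

    @property
    def ratio(self) -> float:
        """Variance ratio sigma2_e / sigma2_u (the BLUP shrinkage ratio)."""
        return self.sigma2_e / self.sigma2_u


@dataclass
class MultiTraitCovariance:
    """Between-trait genetic (G0) and residual (R0) covariance matrices.

    ``V0 = G0 + R0`` is the phenotypic covariance and ``Psi`` its correlation
    matrix.  Both inputs are symmetrized and floored to PSD on construction.
    """

    G0: np.ndarray
    R0: np.ndarray
    V0: np.ndarray = field(init=False)
    Psi: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        G0 = np.asarray(self.G0, dtype=float)
        R0 = np.asarray(self.R0, dtype=float)
        if G0.shape != R0.shape or G0.ndim != 2 or G0.shape[0] != G0.shape[1]:
            raise ValueError("G0 and R0 must be square matrices of equal size")
        self.G0 = nearest_psd(G0)
        self.R0 = nearest_psd(R0)
        self.V0 = self.G0 + self.R0
        d = np.sqrt(np.diag(self.V0))
        self.Psi = self.V0 / np.outer(d, d)
        off = self.Psi[~np.eye(len(d), dtype=bool)]
        if np.any(np.abs(off) >= 1):
            raise ValueError("phenotypic correlations must lie in (-1, 1)")

    @property
    def n_traits(self) -> int:
        return self.G0.shape[0]


@dataclass
class MissingnessPattern:
    """Binary indicator of which complete-data records were observed (1)."""

    r: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r)
        vals = np.unique(self.r)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("missingness pattern entries must be 0/1")
        if not np.any(self.r == 1):
            raise ValueError("missingness pattern has no observed entry")
        self.r = self.r.astype(int)

    @property
    def observed(self) -> np.ndarray:
        return self.r.astype(bool)

    @property
    def n_observed(self) -> int:
        return int(self.r.sum())


# ---------------------------------------------------------------------------
# Relationship-matrix construction
# ---------------------------------------------------------------------------

def genomic_relationship(
    X: np.ndarray | pd.DataFrame, ids: Sequence | None = None
) -> RelationshipMatrix:
    """Build the genomic relationship matrix ``G = XX'/p``.

    Each marker column is centered and divided by its (population) standard
    deviation.  Columns with zero variance carry no signal; they are zeroed
    and excluded from the divisor ``p`` so that ``diag(G)`` stays near 1.

    Parameters
    ----------
    X
        Marker-code matrix (individuals x markers), 0/1 or 0/1/2 codes.
    ids
        Individual identifiers; default integers, or the index of a DataFrame.
    """
    if isinstance(X, pd.DataFrame):
        if ids is None:
            ids = list(X.index)
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("marker matrix must be 2-D with >= 2 individuals")
    if ids is None:
        ids = list(range(X.shape[0]))

    Xc = X - X.mean(axis=0)
    sd = X.std(axis=0)  # ddof=0: population standard deviation
    keep = sd > 0
    p = int(keep.sum())
    if p == 0:
        raise ValueError("no informative markers (all columns have zero variance)")
    Z = np.zeros_like(Xc)
    Z[:, keep] = Xc[:, keep] / sd[keep]
    K = Z @ Z.T / p
    K = (K + K.T) / 2
    return RelationshipMatrix(ids, K, "genomic")


def pedigree_relationship(pedigree: Sequence[tuple]) -> RelationshipMatrix:
    """Numerator (additive) relationship matrix ``A`` by the tabular method.

    Parameters
    ----------
    pedigree
        Iterable of ``(id, sire, dam)`` triples.  Unknown parents are coded
        as ``None``, ``0`` or the empty string.  Founders are assumed
        unrelated and non-inbred.  Rows may arrive in any order; a
        topological order (parents before offspring) is established first.

    Notes
    -----
    The recursion is the standard one: for individual ``i`` with parents
    ``s, d``, ``a_ij = (a_sj + a_dj)/2`` for ``j`` preceding ``i``, and
    ``a_ii = 1 + a_sd/2``.
    """
    def _norm(p):
        return None if p in (None, 0, "0", "", np.nan) else p

    triples = [(i, _norm(s), _norm(d)) for i, s, d in pedigree]
    known = {t[0] for t in triples}
    if len(known) != len(triples):
        raise ValueError("duplicate individual ids in pedigree")

    # topological sort (Kahn); detects cycles
    order: list = []
    placed: set = set()
    pending = list(triples)
    while pending:
        progressed = False
        rest = []
        for t in pending:
            i, s, d = t
            if all(p is None or p in placed or p not in known for p in (s, d)):
                order.append(t)
                placed.add(i)
                progressed = True
            else:
                rest.append(t)
        if not progressed:
            raise ValueError("pedigree contains a cycle (individual is its own ancestor)")
        pending = rest

    ids = [t[0] for t in order]
    index = {v: k for k, v in enumerate(ids)}
    n = len(ids)
    A = np.zeros((n, n))
    for t in order:
        i, s, d = (index[t[0]],
                   index.get(t[1]) if t[1] in known else None,
                   index.get(t[2]) if t[2] in known else None)
        for j in range(i):
            a_sj = A[s, j] if s is not None else 0.0
            a_dj = A[d, j] if d is not None else 0.0
            A[i, j] = A[j, i] = 0.5 * (a_sj + a_dj)
        a_sd = A[s, d] if (s is not None and d is not None) else 0.0
        A[i, i] = 1.0 + 0.5 * a_sd
    return RelationshipMatrix(ids, A, "pedigree")


def nearest_psd(M: np.ndarray, floor: float = PSD_FLOOR) -> np.ndarray:
    """Repair a symmetric matrix to be positive semi-definite.

    The matrix is symmetrized as ``(M + M')/2``, eigendecomposed, and any
    eigenvalue below ``floor * max_eigenvalue`` is replaced by that floor
    value.  Already-PSD matrices are returned unchanged (within 1e-12).
    Idempotent.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("nearest_psd requires a square matrix")
    S = (M + M.T) / 2
    w, V = np.linalg.eigh(S)
    lo = floor * max(w[-1], 0.0)
    if w[0] >= lo:
        return S
    w = np.maximum(w, lo)
    R = (V * w) @ V.T
    return (R + R.T) / 2
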