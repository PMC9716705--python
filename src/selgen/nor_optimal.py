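"""Nor-optimal (stabilizing, centripetal) selection on a multivariate normal.

A Gaussian fitness function ``H(y1) = exp(-0.5 (y1-lambda)' Gamma^-1
(y1-lambda))`` acting on a subset ``y1`` of a multivariate normal vector
leaves the survivors normal, with

    V_s = (Gamma0^- + V^-1)^-1,
    m_s = V_s (Gamma0^- lambda0 + V^-1 m),

where ``Gamma0^-`` is the generalized inverse embedding ``Gamma^-1`` in the
selected block and zeros elsewhere.  In a scalar setting the *coefficient of
centripetal selection* ``S = V/(V + gamma)`` measures the fraction of
variance removed; ``gamma = inf`` means no selection and is represented by an
explicit sentinel (``Gamma=None``) so the limit is exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "NorOptimalSpec",
    "post_selection_distribution",
    "centripetal_coefficient",
    "phenotype_breeding_value_case",
    "NO_SELECTION",
]

#: Sentinel for gamma = infinity (no selection).
NO_SELECTION = None


@dataclass
class NorOptimalSpec:
    """Pre-selection Gaussian plus a Gaussian fitness on selected components.

    m, V
        Pre-selection mean vector and covariance matrix of the full vector.
    sel_idx
        Indices of the components selection acts on (``y1``).
    lambda_opt
        Optimum vector for the selected components.
    Gamma
        Sharpness matrix on the selected block; ``None`` (the
        :data:`NO_SELECTION` sentinel) means gamma = infinity.
    """

    m: np.ndarray
    V: np.ndarray
    sel_idx: np.ndarray
    lambda_opt: np.ndarray | None = None
    Gamma: np.ndarray | None = NO_SELECTION

    def __post_init__(self) -> None:
        self.m = np.atleast_1d(np.asarray(self.m, dtype=float))
        self.V = np.atleast_2d(np.asarray(self.V, dtype=float))
        self.sel_idx = np.atleast_1d(np.asarray(self.sel_idx, dtype=int))
        k = len(self.m)
        if self.V.shape != (k, k):
            raise ValueError("V must be square and match m")
        if np.any(np.linalg.eigvalsh(self.V) < -1e-10):
            raise ValueError("V must be PSD")
        if self.Gamma is not NO_SELECTION:
            self.Gamma = np.atleast_2d(np.asarray(self.Gamma, dtype=float))
            s = len(self.sel_idx)
            if self.Gamma.shape != (s, s):
                raise ValueError("Gamma must match the selected block")
            if np.any(np.linalg.eigvalsh(self.Gamma) <= 0):
                raise ValueError("Gamma must be positive definite")
            if self.lambda_opt is None:
                raise ValueError("lambda_opt required when Gamma is finite")
            self.lambda_opt = np.atleast_1d(np.asarray(self.lambda_opt, dtype=float))
            if len(self.lambda_opt) != s:
                raise ValueError("lambda_opt must match the selected block")

    def gamma0_minus(self) -> np.ndarray:
        """Block-embedded generalized inverse (zeros off the selected block)."""
        k = len(self.m)
        G0 = np.zeros((k, k))
        if self.Gamma is not NO_SELECTION:
            G0[np.ix_(self.sel_idx, self.sel_idx)] = np.linalg.inv(self.Gamma)
        return G0

    def lambda0(self) -> np.ndarray:
        lam0 = np.zeros(len(self.m))
        if self.Gamma is not NO_SELECTION:
            lam0[self.sel_idx] = self.lambda_opt
        return lam0


def post_selection_distribution(spec: NorOptimalSpec) -> tuple[np.ndarray, np.ndarray]:
    """Post-selection mean and covariance ``(m_s, V_s)`` of the full vector."""
    if np.any(np.linalg.eigvalsh(spec.V) <= 0):
        raise np.linalg.LinAlgError("V is singular")
    if spec.Gamma is NO_SELECTION:
        return spec.m.copy(), spec.V.copy()
    G0 = spec.gamma0_minus()
    Vinv = np.linalg.inv(spec.V)
    Vs = np.linalg.inv(G0 + Vinv)
    Vs = (Vs + Vs.T) / 2
    ms = Vs @ (G0 @ spec.lambda0() + Vinv @ spec.m)
    return ms, Vs


def centripetal_coefficient(V: float, gamma: float | None) -> float:
    """Fraction of variance removed by scalar nor-optimal selection.

    ``S = V / (V + gamma)``; ``1 - S = gamma / (V + gamma)`` is the variance
    fraction remaining.  ``gamma`` of ``None``/``inf`` (no selection) gives 0.
    """
    if V <= 0:
        raise ValueError("V must be > 0")
    if gamma is NO_SELECTION or np.isinf(gamma):
        return 0.0
    if gamma <= 0:
        raise ValueError("gamma must be > 0 or infinite")
    return float(V / (V + gamma))


def phenotype_breeding_value_case(
    h2: float, lambda_opt: float, gamma: float | None
) -> dict:
    """Joint and conditional moments of (phenotype, breeding value) after one
    round of phenotypic nor-optimal selection.

    The standardized model is ``y = u + e`` with ``u ~ N(0, h2)``,
    ``e ~ N(0, 1-h2)``, so pre-selection ``(y, u)`` is bivariate normal with
    unit phenotypic variance.  Selection towards ``lambda_opt`` with
    sharpness ``gamma`` gives ``S = 1/(1+gamma)`` and

        E_s(y, u)   = (lambda S, h2 lambda S)
        Var_s(y, u) = [[1-S, h2(1-S)], [h2(1-S), h2(1 - h2 S)]]

    while the conditional distribution ``u | y`` keeps its pre-selection
    parameters ``E(u|y) = h2 y``, ``Var(u|y) = h2 (1-h2)`` — selection on the
    phenotype is ignorable for learning the breeding value from it.
    """
    if not 0 < h2 < 1:
        raise ValueError("h2 must lie in (0, 1)")
    S = centripetal_coefficient(1.0, gamma)
    mean_s = np.array([lambda_opt * S, h2 * lambda_opt * S])
    var_s = np.array(
        [
            [1 - S, h2 * (1 - S)],
            [h2 * (1 - S), h2 * (1 - h2 * S)],
        ]
    )
    return {
        "S": S,
        "mean_s": mean_s,
        "var_s": var_s,
        "cond_slope": h2,       # E_s(u|y) = h2 * y
        "cond_var": h2 * (1 - h2),
    }
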