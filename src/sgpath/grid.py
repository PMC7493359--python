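"""Penalty-grid construction: lambda_max and the logarithmic sequence.

lambda_max is the smallest penalty at which the all-zero penalized block
(together with the unpenalized least-squares fit b0) is optimal.  It is
derived from the stationarity conditions: with g^(l) = (1/n) Z^(l)' r0 and
r0 the residual of the unpenalized baseline fit,

  alpha = 1:      lambda_max = max_j |g_j| / omega_j^F
  alpha = 0:      lambda_max = max_l ||g^(l)||_2 / omega_l^G
  0 < alpha < 1:  per group, the critical lambda solves
                  ||soft_threshold(g^(l), alpha*lam*omega^F)||_2
                      = (1-alpha)*lam*omega_l^G
                  (strictly monotone in lam; solved by bisection);
                  lambda_max is the largest critical value.

The grid is log-equispaced from lambda_max down to xi * lambda_max.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateProblemError
from .problem import GroupWeights, ProblemData
from .prox import soft_threshold

__all__ = [
    "LambdaGrid",
    "unpenalized_baseline",
    "compute_lambda_max",
    "build_lambda_grid",
]

_BISECT_RTOL = 1e-10


@dataclass(frozen=True)
class LambdaGrid:
    """Strictly decreasing, log-equispaced penalty values, length K."""

    values: np.ndarray

    @property
    def lambda_max(self) -> float:
        return float(self.values[0])

    @property
    def lambda_min(self) -> float:
        return float(self.values[-1])

    def __len__(self) -> int:
        return int(self.values.shape[0])


def unpenalized_baseline(problem: ProblemData) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares fit of y on X alone: b0 = argmin ||y - Xb|| and its
    residual r0 = y - X b0.

    The minimum-norm solution is taken if X is rank-deficient; r0 is then
    orthogonal to the column space of X.  With no X, b0 is empty and
    r0 = y.
    """
    if problem.X is None:
        return np.zeros(0), problem.y.copy()
    b0, *_ = np.linalg.lstsq(problem.X, problem.y, rcond=None)
    return b0, problem.y - problem.X @ b0


def _critical_lambda_group(
    g: np.ndarray, wF: np.ndarray, wG: float, alpha: float
) -> float:
    """Smallest lam with ||ST(g, alpha*lam*wF)||_2 <= (1-alpha)*lam*wG,
    i.e. the root of the strictly decreasing function

        phi(lam) = ||ST(g, alpha*lam*wF)||_2 - (1-alpha)*lam*wG.
    """
    if alpha == 1.0:
        return float(np.max(np.abs(g) / wF))
    if alpha == 0.0:
        return float(np.linalg.norm(g) / wG)

    def phi(lam: float) -> float:
        return float(
            np.linalg.norm(soft_threshold(g, alpha * lam * wF))
            - (1.0 - alpha) * lam * wG
        )

    if not np.any(np.abs(g) > 0):
        return 0.0
    # upper bracket: at lam = max |g_j|/(alpha wF_j) the ST term is 0
    hi = float(np.max(np.abs(g) / (alpha * wF)))
    lo = 0.0
    # phi(0) = ||g|| > 0, phi(hi) = -(1-alpha) hi wG < 0
    while hi - lo > _BISECT_RTOL * hi:
        mid = 0.5 * (lo + hi)
        if phi(mid) > 0:
            lo = mid
        else:
            hi = mid
    return hi


def compute_lambda_max(
    problem: ProblemData,
    gw: GroupWeights,
    alpha: float,
    r0: np.ndarray | None = None,
) -> float:
    """Smallest lambda at which (b0, 0) satisfies the optimality conditions.

    Raises DegenerateProblemError if Z' r0 vanishes (y is in the column
    space of X, or Z carries no signal at the baseline).
    """
    if r0 is None:
        _, r0 = unpenalized_baseline(problem)
    g = (problem.Z.T @ r0) / problem.n
    if not np.any(np.abs(g) > 0):
        raise DegenerateProblemError(
            "Z' r0 = 0 at the unpenalized baseline: no finite lambda_max"
        )
    lam = 0.0
    for l in range(problem.n_groups):
        mask = problem.groups == l
        lam_l = _critical_lambda_group(
            g[mask], problem.feature_weights[mask], float(gw.omega[l]), alpha
        )
        lam = max(lam, lam_l)
    return lam


def build_lambda_grid(lambda_max: float, xi: float, K: int) -> LambdaGrid:
    """values_k = lambda_max * xi^(k/(K-1)), k = 0..K-1.

    K = 1 returns the single value lambda_max; xi = 1 a constant sequence.
    """
    if not 0.0 < xi <= 1.0:
        raise ValueError(f"xi must be in (0, 1], got {xi}")
    if K < 1:
        raise ValueError(f"K must be >= 1, got {K}")
    if lambda_max <= 0:
        raise ValueError(f"lambda_max must be > 0, got {lambda_max}")
    if K == 1:
        return LambdaGrid(values=np.array([lambda_max]))
    k = np.arange(K)
    return LambdaGrid(values=lambda_max * xi ** (k / (K - 1)))
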