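"""Independent numerical oracles used by the test suite.

These deliberately avoid the package's proximal machinery: the nonsmooth
objectives are handled by epsilon-smoothing (|x| -> sqrt(x^2 + eps^2),
||v|| -> sqrt(||v||^2 + eps^2)) minimized with L-BFGS-B under a
continuation schedule driving eps to ~1e-14.  The smoothing bias of the
objective is bounded by eps times the sum of penalty coefficients, so the
final objective values are accurate to far below the tolerances the tests
assert.  For the prox oracle (which needs 1e-6 accuracy in the minimizer
itself, not just the objective) a support-polish stage re-minimizes the
true objective restricted to the detected support, where it is smooth.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize

_EPS_SCHEDULE = (1e-2, 1e-4, 1e-6, 1e-8, 1e-10, 1e-12, 1e-14)


def _group_masks(groups: np.ndarray) -> list[np.ndarray]:
    g = np.asarray(groups)
    return [g == l for l in range(int(g.max()) + 1)]


def prox_objective(
    x: np.ndarray, v: np.ndarray, l1: np.ndarray, tau_group: np.ndarray,
    groups: np.ndarray,
) -> float:
    """0.5||x - v||^2 + sum tau_j |x_j| + sum_l tau_l ||x^(l)||_2."""
    val = 0.5 * float(np.sum((x - v) ** 2)) + float(np.sum(l1 * np.abs(x)))
    for l, m in enumerate(_group_masks(groups)):
        val += float(tau_group[l]) * float(np.linalg.norm(x[m]))
    return val


def prox_oracle(
    v: np.ndarray, l1: np.ndarray, tau_group: np.ndarray, groups: np.ndarray
) -> np.ndarray:
    """Brute-force minimizer of the prox objective (small p only).

    Enumerates every one of the 2^p candidate supports, minimizes the true
    objective restricted to that support with L-BFGS-B (on the correct
    support the objective is smooth at the minimizer: every kept
    coordinate and group norm is non-zero there), and returns the
    candidate with the lowest true objective.  The prox objective is
    1-strongly convex, so an objective gap of g bounds the minimizer
    error by sqrt(2 g); the winning candidate's gap is at quadrature
    accuracy (~1e-14), i.e. minimizer accuracy ~1e-7 or better.
    """
    v = np.asarray(v, dtype=float)
    p = v.shape[0]
    if p > 12:
        raise ValueError("prox_oracle enumerates supports; use p <= 12")
    masks = _group_masks(groups)

    def polish(support: np.ndarray) -> np.ndarray:
        if not np.any(support):
            return np.zeros_like(v)

        def fg_support(xs):
            full = np.zeros_like(v)
            full[support] = xs
            d = full - v
            f = 0.5 * d @ d + np.sum(l1 * np.abs(full))
            gfull = d + l1 * np.sign(full)
            for l, m in enumerate(masks):
                nl = np.linalg.norm(full[m])
                if nl > 0:
                    f += tau_group[l] * nl
                    gfull[m] += tau_group[l] * full[m] / nl
            return f, gfull[support]

        res = minimize(fg_support, v[support], jac=True, method="L-BFGS-B",
                       options={"maxiter": 5000, "ftol": 1e-18, "gtol": 1e-13})
        out = np.zeros_like(v)
        out[support] = res.x
        return out

    best, best_val = None, np.inf
    for mask_bits in range(2 ** p):
        support = np.array(
            [(mask_bits >> j) & 1 == 1 for j in range(p)], dtype=bool
        )
        cand = polish(support)
        val = prox_objective(cand, v, l1, tau_group, groups)
        if val < best_val:
            best, best_val = cand, val
    return best


def full_objective(
    b, u, y, X, Z, groups, wF, wG, lam, alpha
) -> float:
    """The solver's (nonsmooth) objective, re-implemented independently."""
    n = y.shape[0]
    r = y - Z @ u - (X @ b if X is not None else 0.0)
    val = 0.5 * float(r @ r) / n + alpha * lam * float(np.sum(wF * np.abs(u)))
    for l, m in enumerate(_group_masks(groups)):
        val += (1.0 - alpha) * lam * float(wG[l]) * float(np.linalg.norm(u[m]))
    return val


def solve_oracle(
    y, X, Z, groups, wF, wG, lam, alpha, x0=None
) -> tuple[np.ndarray, np.ndarray, float]:
    """Smoothed-objective minimizer of the full problem.

    Returns (b, u, objective) with the objective evaluated on the true
    (nonsmooth) function at the smoothed minimizer.
    """
    n, p = Z.shape
    q = 0 if X is None else X.shape[1]
    masks = _group_masks(groups)

    def make_fg(eps: float):
        def fg(x):
            b, u = x[:q], x[q:]
            r = y - Z @ u - (X @ b if X is not None else 0.0)
            f = 0.5 * (r @ r) / n
            gb = -(X.T @ r) / n if X is not None else np.zeros(0)
            gu = -(Z.T @ r) / n
            au = np.sqrt(u * u + eps * eps)
            f += alpha * lam * np.sum(wF * au)
            gu = gu + alpha * lam * wF * u / au
            for l, m in enumerate(masks):
                nl = np.sqrt(u[m] @ u[m] + eps * eps)
                f += (1.0 - alpha) * lam * wG[l] * nl
                gu[m] += (1.0 - alpha) * lam * wG[l] * u[m] / nl
            return f, np.concatenate([gb, gu])
        return fg

    x = np.zeros(q + p) if x0 is None else np.asarray(x0, dtype=float).copy()
    for eps in _EPS_SCHEDULE:
        res = minimize(make_fg(eps), x, jac=True, method="L-BFGS-B",
                       options={"maxiter": 5000, "ftol": 1e-18, "gtol": 1e-12})
        x = res.x
    b, u = x[:q], x[q:]
    return b, u, full_objective(b, u, y, X, Z, groups, wF, wG, lam, alpha)
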