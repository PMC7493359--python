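"""Proximal gradient descent with backtracking, and the warm-started path.

A single penalty value is solved by plain (non-accelerated) PGD: each
iteration takes a gradient step on the smooth goodness-of-fit term and
applies the sparse-group proximal map to the penalized block.  The step
size is found by backtracking line search against the quadratic
majorization

    f(x+) <= f(x) + grad f(x)'(x+ - x) + (1/2t) ||x+ - x||^2

on the smooth part f; on rejection the step is multiplied by ``shrink``.
Iteration stops when the relative-accuracy criterion

    || (b,u)^[k] - (b,u)^[k-1] ||_inf  /  || (b,u)^[k] ||_2  <=  eps_rel

holds (at least one iteration is always performed; an all-zero iterate
satisfies the criterion only if the numerator is also zero), or when
``max_iter`` is reached — non-convergence is flagged, not raised.

The full regularization path solves the decreasing lambda grid with warm
starts: the solution at one lambda initializes the next, and the accepted
step size carries over.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import LambdaGrid, build_lambda_grid, compute_lambda_max, unpenalized_baseline
from .problem import (
    CoefficientState,
    GroupWeights,
    Hyperparameters,
    ProblemData,
    compute_group_weights,
    evaluate_objective,
    smooth_gradient,
    smooth_objective,
)
from .prox import ProxThresholds, soft_threshold, sparse_group_prox
from .errors import LineSearchError

__all__ = [
    "SolveDiagnostics",
    "PathResult",
    "backtracking_step",
    "solve_single",
    "kkt_residual",
    "fit_path",
]

_STEP_FLOOR = 1e-30


@dataclass
class SolveDiagnostics:
    """Per-lambda solve record: iteration count, convergence flag, last
    accepted step, the (nonincreasing) objective trace, and the KKT
    stationarity residual at the returned iterate."""

    iterations: int
    converged: bool
    final_step: float
    objective_trace: np.ndarray
    kkt_residual: float


@dataclass
class PathResult:
    """Full regularization path: K states and diagnostics over the grid."""

    grid: LambdaGrid
    states: list[CoefficientState]
    diagnostics: list[SolveDiagnostics]
    alpha: float
    group_labels: np.ndarray            # L original labels
    feature_group_labels: np.ndarray    # per-feature original labels
    feature_ids: list[str]
    unpenalized_ids: list[str]

    def __len__(self) -> int:
        return len(self.states)

    def nonzero_counts(self) -> np.ndarray:
        """Exact count of non-zero penalized coefficients per grid point."""
        return np.array([int(np.count_nonzero(s.u)) for s in self.states])

    def coefficients(self) -> np.ndarray:
        """(K, q + p) array of concatenated (b, u) estimates."""
        return np.stack([s.concat() for s in self.states])


def backtracking_step(
    problem: ProblemData,
    gw: GroupWeights,
    state: CoefficientState,
    lam: float,
    alpha: float,
    t: float,
    shrink: float,
) -> tuple[CoefficientState, float]:
    """One prox-gradient step with backtracking; returns (new_state, t).

    Raises LineSearchError if t underflows below 1e-30.
    """
    gb, gu = smooth_gradient(problem, state)
    f0 = smooth_objective(problem, state)
    # absolute slack guards against ties lost to rounding near a fixed point
    slack = 1e-15 * (1.0 + abs(f0))
    while True:
        b_new = state.b - t * gb
        thr = ProxThresholds.from_penalty(
            t, lam, alpha, problem.feature_weights, gw.omega
        )
        u_new = sparse_group_prox(
            state.u - t * gu, thr, problem.groups, problem.n_groups
        )
        cand = CoefficientState(b_new, u_new)
        db = b_new - state.b
        du = u_new - state.u
        lin = float(gb @ db + gu @ du)
        quad = 0.5 * (float(db @ db) + float(du @ du)) / t
        if smooth_objective(problem, cand) <= f0 + lin + quad + slack:
            return cand, t
        t *= shrink
        if t < _STEP_FLOOR:
            raise LineSearchError("backtracking step underflow (t < 1e-30)")


def solve_single(
    problem: ProblemData,
    gw: GroupWeights,
    lam: float,
    alpha: float,
    init: CoefficientState,
    hp: Hyperparameters,
    step: float | None = None,
) -> tuple[CoefficientState, SolveDiagnostics]:
    """PGD at one penalty value, from ``init``, until the relative-accuracy
    criterion holds or ``hp.max_iter`` iterations are spent.

    ``step`` overrides ``hp.step0`` as the initial line-search step (used
    by the warm-started path to carry the accepted step across lambdas).
    """
    state = init.copy()
    t = hp.step0 if step is None else step
    trace = [evaluate_objective(problem, gw, state, lam, alpha)]
    converged = False
    k = 0
    while k < hp.max_iter:
        new_state, t = backtracking_step(problem, gw, state, lam, alpha, t, hp.shrink)
        k += 1
        trace.append(evaluate_objective(problem, gw, new_state, lam, alpha))
        num = float(np.max(np.abs(new_state.concat() - state.concat())))
        den = float(np.linalg.norm(new_state.concat()))
        state = new_state
        if den == 0.0:
            met = num == 0.0
        else:
            met = num / den <= hp.eps_rel
        if met:
            converged = True
            break
    diag = SolveDiagnostics(
        iterations=k,
        converged=converged,
        final_step=t,
        objective_trace=np.asarray(trace),
        kkt_residual=kkt_residual(problem, gw, state, lam, alpha),
    )
    return state, diag


def kkt_residual(
    problem: ProblemData,
    gw: GroupWeights,
    state: CoefficientState,
    lam: float,
    alpha: float,
) -> float:
    """Max-norm violation of the stationarity conditions at (b, u).

    b block: the exact gradient must vanish.  For each group of u, with
    c = (1/n) Z^(l)' r (minus the smooth gradient):

    * zero group: c must lie in the Minkowski sum of the weighted l-inf
      ball (radius alpha*lam*omega_j^F per coordinate) and the l2 ball of
      radius (1-alpha)*lam*omega_l^G; the violation is the Euclidean
      distance to that set, max(0, ||ST(c, alpha*lam*wF)|| - (1-alpha)*lam*wG).
    * non-zero group: coordinates with u_j != 0 must satisfy exact
      stationarity; zero coordinates need |c_j| <= alpha*lam*omega_j^F.
    """
    r = problem.y - problem.predict(state.b, state.u)
    res = 0.0
    if problem.X is not None:
        res = float(np.max(np.abs(problem.X.T @ r))) / problem.n
    c_all = (problem.Z.T @ r) / problem.n
    for l in range(problem.n_groups):
        mask = problem.groups == l
        c = c_all[mask]
        wF = problem.feature_weights[mask]
        wG = float(gw.omega[l])
        ul = state.u[mask]
        nrm = float(np.linalg.norm(ul))
        if nrm == 0.0:
            viol = max(
                0.0,
                float(np.linalg.norm(soft_threshold(c, alpha * lam * wF)))
                - (1.0 - alpha) * lam * wG,
            )
            res = max(res, viol)
        else:
            grp_sub = (1.0 - alpha) * lam * wG * ul / nrm
            nz = ul != 0.0
            if np.any(nz):
                stat = c[nz] - alpha * lam * wF[nz] * np.sign(ul[nz]) - grp_sub[nz]
                res = max(res, float(np.max(np.abs(stat))))
            if np.any(~nz):
                over = np.abs(c[~nz]) - alpha * lam * wF[~nz]
                res = max(res, float(np.max(np.maximum(over, 0.0))))
    return res


def fit_path(
    problem: ProblemData,
    hp: Hyperparameters | None = None,
    gw: GroupWeights | None = None,
) -> PathResult:
    """Solve the full warm-started regularization path.

    The grid runs from lambda_max (where the penalized block is exactly
    zero) down to xi * lambda_max on a log scale.  Grid point 0 starts at
    (b0, 0) with b0 the unpenalized least-squares fit; each later point
    starts at the previous solution, seeding the line search with the
    previously accepted step.
    """
    if not problem.validated:
        from .problem import validate_problem

        problem = validate_problem(problem)
    if hp is None:
        hp = Hyperparameters()
    if gw is None:
        gw = compute_group_weights(
            problem.feature_weights, problem.groups, problem.n_groups
        )
    b0, r0 = unpenalized_baseline(problem)
    lam_max = compute_lambda_max(problem, gw, hp.alpha, r0=r0)
    grid = build_lambda_grid(lam_max, hp.xi, hp.n_lambda)

    states: list[CoefficientState] = []
    diags: list[SolveDiagnostics] = []
    state = CoefficientState(b0, np.zeros(problem.p))
    step: float | None = None
    for lam in grid.values:
        state, diag = solve_single(
            problem, gw, float(lam), hp.alpha, state, hp, step=step
        )
        step = diag.final_step
        states.append(state)
        diags.append(diag)

    feature_ids = problem.feature_ids or [f"f{j + 1}" for j in range(problem.p)]
    unpen_ids = problem.unpenalized_ids or [f"b{j + 1}" for j in range(problem.q)]
    return PathResult(
        grid=grid,
        states=states,
        diagnostics=diags,
        alpha=hp.alpha,
        group_labels=problem.group_labels,
        feature_group_labels=problem.group_labels[problem.groups],
        feature_ids=feature_ids,
        unpenalized_ids=unpen_ids,
    )
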