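"""Problem representation, validation, objective and smooth gradient.

The model is a linear regression with an unpenalized effect block ``b``
(design ``X``, n x q, possibly absent) and a penalized block ``u``
(design ``Z``, n x p) whose features are partitioned into L non-overlapping
groups.  The objective minimized over (b, u) is

    (1/2n) ||y - Xb - Zu||_2^2
        + alpha * lam * sum_j omega_j^F |u_j|
        + (1 - alpha) * lam * sum_l omega_l^G ||u^(l)||_2

with per-feature weights ``omega^F`` (default all ones) and group weights

    omega_l^G = sqrt(p_l * mean_{j in l} omega_j^F),

which reduce to the classical sqrt(p_l) factor for unit feature weights.
``alpha`` in [0, 1] mixes the lasso (alpha = 1) and group-lasso (alpha = 0)
penalties; intermediate values give the sparse-group lasso.

No implicit centering or scaling is performed: estimates are reported on
the input scale.  An intercept, if wanted, is a ones-column in ``X``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import (
    DimensionMismatchError,
    EmptyGroupError,
    NonFiniteError,
    NonPositiveWeightError,
)

__all__ = [
    "ProblemData",
    "GroupWeights",
    "Hyperparameters",
    "CoefficientState",
    "validate_problem",
    "compute_group_weights",
    "evaluate_objective",
    "penalty_value",
    "smooth_objective",
    "smooth_gradient",
]


@dataclass
class ProblemData:
    """A (possibly not yet validated) problem instance.

    Parameters
    ----------
    y : (n,) response vector.
    Z : (n, p) design matrix of the penalized features.
    groups : (p,) group labels (arbitrary hashables: ints or strings).
        After validation this holds contiguous integer codes 0..L-1 in
        first-appearance order; the original labels are kept in
        ``group_labels``.
    X : (n, q) design of unpenalized effects, or None for q = 0.
    feature_weights : (p,) positive weights omega^F, or None for all ones.
    feature_ids : optional identifiers for the p penalized features.
    unpenalized_ids : optional identifiers for the q unpenalized effects.
    """

    y: np.ndarray
    Z: np.ndarray
    groups: np.ndarray
    X: np.ndarray | None = None
    feature_weights: np.ndarray | None = None
    feature_ids: list[str] | None = None
    unpenalized_ids: list[str] | None = None
    group_labels: np.ndarray | None = field(default=None)
    validated: bool = field(default=False)

    # -- shapes ----------------------------------------------------------
    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def p(self) -> int:
        return self.Z.shape[1]

    @property
    def q(self) -> int:
        return 0 if self.X is None else self.X.shape[1]

    @property
    def n_groups(self) -> int:
        if not self.validated:
            raise ValueError("n_groups requires a validated problem")
        return int(self.group_labels.shape[0])

    @property
    def group_sizes(self) -> np.ndarray:
        return np.bincount(self.groups, minlength=self.n_groups)

    def predict(self, b: np.ndarray, u: np.ndarray) -> np.ndarray:
        """Fitted values Xb + Zu (Xb == 0 when q = 0)."""
        yhat = self.Z @ u
        if self.X is not None:
            yhat = yhat + self.X @ b
        return yhat


@dataclass(frozen=True)
class GroupWeights:
    """Per-group weights omega^G, length L."""

    omega: np.ndarray


@dataclass(frozen=True)
class Hyperparameters:
    """Solver and path controls.

    alpha : penalty mixing parameter in [0, 1]; 1 = lasso, 0 = group lasso.
    xi : ratio lambda_min / lambda_max, in (0, 1].
    n_lambda : grid length K.
    eps_rel : relative accuracy of the stopping criterion.
    max_iter : iteration cap per lambda (non-convergence is flagged, not
        raised).
    step0 : initial backtracking step size.
    shrink : backtracking shrink factor in (0, 1).
    """

    alpha: float = 0.95
    xi: float = 0.001
    n_lambda: int = 50
    eps_rel: float = 1e-4
    max_iter: int = 1000
    step0: float = 1.0
    shrink: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if not 0.0 < self.xi <= 1.0:
            raise ValueError(f"xi must be in (0, 1], got {self.xi}")
        if self.n_lambda < 1:
            raise ValueError(f"n_lambda must be >= 1, got {self.n_lambda}")
        if self.eps_rel <= 0:
            raise ValueError(f"eps_rel must be > 0, got {self.eps_rel}")
        if self.max_iter < 1:
            raise ValueError(f"max_iter must be >= 1, got {self.max_iter}")
        if self.step0 <= 0:
            raise ValueError(f"step0 must be > 0, got {self.step0}")
        if not 0.0 < self.shrink < 1.0:
            raise ValueError(f"shrink must be in (0, 1), got {self.shrink}")


@dataclass
class CoefficientState:
    """One iterate (b, u); b has length q, u has length p."""

    b: np.ndarray
    u: np.ndarray

    def copy(self) -> "CoefficientState":
        return CoefficientState(self.b.copy(), self.u.copy())

    def concat(self) -> np.ndarray:
        return np.concatenate([self.b, self.u])

    def group_view(self, problem: ProblemData, l: int) -> np.ndarray:
        """Entries of u belonging to group ``l`` (validated codes)."""
        return self.u[problem.groups == l]


def _as_float_array(a, name: str, ndim: int) -> np.ndarray:
    arr = np.asarray(a, dtype=float)
    if arr.ndim != ndim:
        raise DimensionMismatchError(
            f"{name} must be {ndim}-dimensional, got shape {arr.shape}"
        )
    return arr


def validate_problem(raw: ProblemData) -> ProblemData:
    """Check invariants and return a validated copy.

    Group labels are relabelled to contiguous codes 0..L-1 in order of
    first appearance; the original labels are stored in ``group_labels``
    so output files can report them verbatim.

    Raises
    ------
    DimensionMismatchError, NonPositiveWeightError, NonFiniteError,
    EmptyGroupError
    """
    y = _as_float_array(raw.y, "y", 1)
    Z = _as_float_array(raw.Z, "Z", 2)
    n = y.shape[0]
    p = Z.shape[1]
    if p < 1:
        raise DimensionMismatchError("Z must have at least one column")
    if Z.shape[0] != n:
        raise DimensionMismatchError(
            f"Z has {Z.shape[0]} rows but y has length {n}"
        )
    X = None
    if raw.X is not None:
        X = _as_float_array(raw.X, "X", 2)
        if X.shape[1] == 0:
            X = None
        elif X.shape[0] != n:
            raise DimensionMismatchError(
                f"X has {X.shape[0]} rows but y has length {n}"
            )

    groups_raw = np.asarray(raw.groups)
    if groups_raw.ndim != 1 or groups_raw.shape[0] != p:
        raise DimensionMismatchError(
            f"groups must have length p = {p}, got shape {groups_raw.shape}"
        )
    # contiguous codes in first-appearance order
    labels: list = []
    seen: dict = {}
    codes = np.empty(p, dtype=np.intp)
    for j, g in enumerate(groups_raw.tolist()):
        if g not in seen:
            seen[g] = len(labels)
            labels.append(g)
        codes[j] = seen[g]
    group_labels = np.asarray(labels)
    L = len(labels)
    if np.any(np.bincount(codes, minlength=L) == 0):  # pragma: no cover
        raise EmptyGroupError("a group has no features after relabelling")

    if raw.feature_weights is None:
        w = np.ones(p)
    else:
        w = _as_float_array(raw.feature_weights, "feature_weights", 1)
        if w.shape[0] != p:
            raise DimensionMismatchError(
                f"feature_weights must have length p = {p}, got {w.shape[0]}"
            )
        if np.any(~np.isfinite(w)):
            raise NonFiniteError("feature_weights contains non-finite entries")
        if np.any(w <= 0):
            raise NonPositiveWeightError(
                "all feature weights must be strictly positive"
            )

    for name, arr in (("y", y), ("Z", Z)) + ((("X", X),) if X is not None else ()):
        if np.any(~np.isfinite(arr)):
            raise NonFiniteError(f"{name} contains non-finite entries")

    return replace(
        raw,
        y=y,
        Z=Z,
        X=X,
        groups=codes,
        feature_weights=w,
        group_labels=group_labels,
        validated=True,
    )


def compute_group_weights(
    feature_weights: np.ndarray, groups: np.ndarray, n_groups: int | None = None
) -> GroupWeights:
    """Group weights omega_l^G = sqrt(p_l * mean_{j in l} omega_j^F).

    With unit feature weights this is sqrt(p_l).  ``groups`` must hold
    validated contiguous codes.
    """
    w = np.asarray(feature_weights, dtype=float)
    g = np.asarray(groups)
    L = int(g.max()) + 1 if n_groups is None else n_groups
    sums = np.bincount(g, weights=w, minlength=L)
    # p_l * mean = sum of weights in the group
    return GroupWeights(omega=np.sqrt(sums))


def penalty_value(
    problem: ProblemData,
    gw: GroupWeights,
    u: np.ndarray,
    lam: float,
    alpha: float,
) -> float:
    """The nonsmooth penalty alpha*lam*sum w|u| + (1-alpha)*lam*sum wG||u^(l)||."""
    l1 = float(np.sum(problem.feature_weights * np.abs(u)))
    sq = np.bincount(problem.groups, weights=u * u, minlength=problem.n_groups)
    l21 = float(np.sum(gw.omega * np.sqrt(sq)))
    return alpha * lam * l1 + (1.0 - alpha) * lam * l21


def smooth_objective(problem: ProblemData, state: CoefficientState) -> float:
    """The goodness-of-fit term (1/2n)||y - Xb - Zu||^2."""
    r = problem.y - problem.predict(state.b, state.u)
    return 0.5 * float(r @ r) / problem.n


def evaluate_objective(
    problem: ProblemData,
    gw: GroupWeights,
    state: CoefficientState,
    lam: float,
    alpha: float,
) -> float:
    """Full objective value at (b, u); equals the unweighted form when all
    feature weights are one."""
    return smooth_objective(problem, state) + penalty_value(
        problem, gw, state.u, lam, alpha
    )


def smooth_gradient(
    problem: ProblemData, state: CoefficientState
) -> tuple[np.ndarray, np.ndarray]:
    """Gradient of the smooth term: (-(1/n) X'r, -(1/n) Z'r), r = y - Xb - Zu."""
    r = problem.y - problem.predict(state.b, state.u)
    gb = np.zeros(0) if problem.X is None else -(problem.X.T @ r) / problem.n
    gu = -(problem.Z.T @ r) / problem.n
    return gb, gu
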