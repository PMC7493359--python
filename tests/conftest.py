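import numpy as np
import pytest

from sgpath import (
    CoefficientState,
    ProblemData,
    compute_group_weights,
    validate_problem,
)


def make_random_problem(
    rng: np.random.Generator,
    n: int = 12,
    p: int = 6,
    L: int = 3,
    with_x: bool = True,
    weights: bool = False,
):
    """A small random validated instance with signal in the first group."""
    Z = rng.normal(size=(n, p))
    X = np.column_stack([np.ones(n), rng.normal(size=n)]) if with_x else None
    groups = np.sort(rng.integers(0, L, size=p))
    groups = np.unique(groups, return_inverse=True)[1]  # ensure contiguous codes
    u = np.zeros(p)
    u[groups == 0] = rng.normal(size=int(np.sum(groups == 0)))
    y = Z @ u + rng.normal(scale=0.5, size=n)
    w = rng.uniform(0.5, 2.0, size=p) if weights else None
    problem = validate_problem(
        ProblemData(y=y, Z=Z, groups=groups, X=X, feature_weights=w)
    )
    gw = compute_group_weights(problem.feature_weights, problem.groups,
                               problem.n_groups)
    return problem, gw


def random_state(rng: np.random.Generator, problem) -> CoefficientState:
    return CoefficientState(
        b=rng.normal(size=problem.q), u=rng.normal(size=problem.p)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
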