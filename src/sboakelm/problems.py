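"""Box-bounded minimization problems and a built-in analytic test-function suite.

The suite provides classic continuous benchmarks (Sphere, Rosenbrock,
Rastrigin, Ackley, Griewank, Levy, Schwefel 2.26) at their conventional
bounds, each with its known global optimum recorded, plus a seeded
shift/rotate transform that emulates the structure of shifted-rotated
competition benchmarks without external data files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Tuple

import numpy as np

__all__ = [
    "SearchSpace",
    "ObjectiveProblem",
    "make_standard_suite",
    "make_shifted_rotated",
    "evaluate_batch",
    "get_problem",
]


@dataclass(frozen=True)
class SearchSpace:
    """A D-dimensional box [lb, ub]."""

    dim: int
    lb: np.ndarray
    ub: np.ndarray

    def __post_init__(self) -> None:
        if self.dim < 1:
            raise ValueError(f"dim must be >= 1, got {self.dim}")
        lb = np.broadcast_to(np.asarray(self.lb, dtype=float), (self.dim,)).copy()
        ub = np.broadcast_to(np.asarray(self.ub, dtype=float), (self.dim,)).copy()
        object.__setattr__(self, "lb", lb)
        object.__setattr__(self, "ub", ub)
        if np.any(lb > ub):
            raise ValueError("lower bounds must not exceed upper bounds")

    @classmethod
    def cube(cls, dim: int, lo: float, hi: float) -> "SearchSpace":
        return cls(dim, np.full(dim, lo), np.full(dim, hi))


@dataclass
class ObjectiveProblem:
    """A named minimization problem over a box, with an optional known optimum.

    ``objective`` maps a length-D vector to a scalar and must be defined on
    all of R^D (repair operators may evaluate slightly out of the box before
    clipping).  ``n_evaluations`` counts objective calls made through
    :func:`evaluate_batch`.
    """

    name: str
    space: SearchSpace
    objective: Callable[[np.ndarray], float]
    known_optimum: Optional[Tuple[np.ndarray, float]] = None
    n_evaluations: int = field(default=0, compare=False)


def _sphere(x: np.ndarray) -> float:
    return float(np.sum(x * x))


def _rosenbrock(x: np.ndarray) -> float:
    return float(np.sum(100.0 * (x[1:] - x[:-1] ** 2) ** 2 + (1.0 - x[:-1]) ** 2))


def _rastrigin(x: np.ndarray) -> float:
    return float(10.0 * x.size + np.sum(x * x - 10.0 * np.cos(2.0 * np.pi * x)))


def _ackley(x: np.ndarray) -> float:
    d = x.size
    return float(
        -20.0 * np.exp(-0.2 * np.sqrt(np.sum(x * x) / d))
        - np.exp(np.sum(np.cos(2.0 * np.pi * x)) / d)
        + 20.0
        + np.e
    )


def _griewank(x: np.ndarray) -> float:
    i = np.arange(1, x.size + 1, dtype=float)
    return float(1.0 + np.sum(x * x) / 4000.0 - np.prod(np.cos(x / np.sqrt(i))))


def _levy(x: np.ndarray) -> float:
    w = 1.0 + (x - 1.0) / 4.0
    head = np.sin(np.pi * w[0]) ** 2
    mid = np.sum((w[:-1] - 1.0) ** 2 * (1.0 + 10.0 * np.sin(np.pi * w[:-1] + 1.0) ** 2))
    tail = (w[-1] - 1.0) ** 2 * (1.0 + np.sin(2.0 * np.pi * w[-1]) ** 2)
    return float(head + mid + tail)


_SCHWEFEL_OPT = 420.968746227503603  # argmin of -x*sin(sqrt(|x|)) on [-500, 500]


def _schwefel226(x: np.ndarray) -> float:
    return float(418.9828872724339 * x.size - np.sum(x * np.sin(np.sqrt(np.abs(x)))))


# name -> (callable, conventional bounds (lo, hi), optimum location builder)
_SUITE = {
    "sphere": (_sphere, (-100.0, 100.0), lambda d: np.zeros(d)),
    "rosenbrock": (_rosenbrock, (-30.0, 30.0), lambda d: np.ones(d)),
    "rastrigin": (_rastrigin, (-5.12, 5.12), lambda d: np.zeros(d)),
    "ackley": (_ackley, (-32.768, 32.768), lambda d: np.zeros(d)),
    "griewank": (_griewank, (-600.0, 600.0), lambda d: np.zeros(d)),
    "levy": (_levy, (-10.0, 10.0), lambda d: np.ones(d)),
    "schwefel226": (_schwefel226, (-500.0, 500.0), lambda d: np.full(d, _SCHWEFEL_OPT)),
}


def get_problem(name: str, dim: int) -> ObjectiveProblem:
    """Build one suite problem by (case-insensitive) name."""
    key = name.strip().lower()
    if key not in _SUITE:
        raise KeyError(f"unknown test function {name!r}; choose from {sorted(_SUITE)}")
    if dim < 1:
        raise ValueError(f"dim must be >= 1, got {dim}")
    fn, (lo, hi), opt_loc = _SUITE[key]
    loc = opt_loc(dim)
    # Schwefel's optimum value is analytically 0 but only to ~1e-13 per
    # dimension with the tabulated constants; record the evaluated value.
    val = fn(loc) if key == "schwefel226" else 0.0
    return ObjectiveProblem(
        name=key,
        space=SearchSpace.cube(dim, lo, hi),
        objective=fn,
        known_optimum=(loc, val),
    )


def make_standard_suite(dim: int) -> list[ObjectiveProblem]:
    """All built-in benchmark problems at dimension ``dim``."""
    if dim < 1:
        raise ValueError(f"dim must be >= 1, got {dim}")
    return [get_problem(name, dim) for name in _SUITE]


def make_shifted_rotated(problem: ObjectiveProblem, seed: int) -> ObjectiveProblem:
    """Seeded shift + orthogonal rotation of a problem with its optimum at the origin.

    Returns the problem ``x -> f(Q (x - s))`` where ``Q`` is the (sign-fixed)
    Q-factor of a seeded Gaussian matrix and ``s`` is a seeded uniform shift
    inside the central 80% of the box.  The optimum moves to ``s``; its value
    is unchanged by orthogonal invariance.
    """
    if problem.known_optimum is None or not np.allclose(problem.known_optimum[0], 0.0):
        raise ValueError("make_shifted_rotated requires a known optimum at the origin")
    d = problem.space.dim
    rng = np.random.default_rng(seed)
    q, r = np.linalg.qr(rng.standard_normal((d, d)))
    q = q * np.sign(np.diag(r))  # canonical sign => deterministic across BLAS builds
    lb, ub = problem.space.lb, problem.space.ub
    s = lb + (0.1 + 0.8 * rng.random(d)) * (ub - lb)
    inner = problem.objective

    def shifted(x: np.ndarray, _q=q, _s=s) -> float:
        return inner(_q @ (np.asarray(x, dtype=float) - _s))

    return ObjectiveProblem(
        name=f"{problem.name}_shifted_rotated",
        space=problem.space,
        objective=shifted,
        known_optimum=(s, problem.known_optimum[1]),
    )


def evaluate_batch(problem: ObjectiveProblem, positions: np.ndarray) -> np.ndarray:
    """Evaluate the objective on each row; increments the problem's counter."""
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    if positions.size == 0:
        return np.empty(0)
    if positions.shape[1] != problem.space.dim:
        raise ValueError(
            f"positions have dimension {positions.shape[1]}, "
            f"problem expects {problem.space.dim}"
        )
    out = np.array([problem.objective(row) for row in positions], dtype=float)
    problem.n_evaluations += positions.shape[0]
    return out
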