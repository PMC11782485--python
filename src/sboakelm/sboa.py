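"""Secretary Bird Optimization Algorithm (SBOA): base primitives and runner.

SBOA is a population metaheuristic modelled on the hunting and escape
behaviour of secretary birds.  Each iteration applies

* a three-stage **hunting** (exploration) update — differential moves toward
  random peers in the first third of the run, a Brownian-scaled move around
  the best solution in the middle third, and a damped Lévy-flight move
  around the best solution in the final third — followed by greedy
  accept/reject, then
* a two-branch **escape** (exploitation) update — either a contraction
  toward the best solution or a camouflage move toward a random peer —
  again followed by greedy accept/reject.

Randomness contract: every run owns a single ``numpy.random.Generator``
seeded from ``OptimizerConfig.seed``; all draws consume that stream in the
fixed order documented in the phase functions, so identical seeds give
bit-identical trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .problems import ObjectiveProblem, SearchSpace, evaluate_batch

__all__ = [
    "OptimizerConfig",
    "SwarmState",
    "OptimizationResult",
    "initialize_population",
    "levy_flight",
    "hunting_update_sboa",
    "escape_update",
    "greedy_select",
    "clip_to_bounds",
    "run_sboa",
    "run_reference_pso",
]

VARIANTS = ("SBOA", "PSBOA", "DSBOA", "QSBOA", "QHSBOA", "PSO")

#: strategy flags (pso, dynamic boundary, quantum mutation) per variant
_VARIANT_FLAGS = {
    "SBOA": (False, False, False),
    "PSBOA": (True, False, False),
    "DSBOA": (False, True, False),
    "QSBOA": (False, False, True),
    "QHSBOA": (True, True, True),
}


@dataclass
class OptimizerConfig:
    """Run configuration shared by all optimizer variants.

    Defaults follow the benchmark protocol: population 30, 500 iterations.
    ``c1``/``c2`` are the PSO learning factors used by the PSO search
    mechanism (both 2 for the enhanced variants); the reference PSO uses its
    own conventional constants.
    """

    pop_size: int = 30
    max_iter: int = 500
    seed: int = 0
    variant: str = "SBOA"
    c1: float = 2.0
    c2: float = 2.0
    #: anchor of the dynamic boundary repair: "pbest" (per-individual) or "gbest"
    boundary_anchor: str = "pbest"

    def __post_init__(self) -> None:
        if self.pop_size < 2:
            raise ValueError("pop_size must be >= 2")
        if self.max_iter < 3:
            raise ValueError("max_iter must be >= 3 (three hunting stages)")
        if self.c1 < 0 or self.c2 < 0:
            raise ValueError("learning factors must be non-negative")
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; choose from {VARIANTS}")
        if self.boundary_anchor not in ("pbest", "gbest"):
            raise ValueError("boundary_anchor must be 'pbest' or 'gbest'")

    def strategy_flags(self) -> tuple[bool, bool, bool]:
        if self.variant == "PSO":
            raise ValueError("the reference PSO has no SBOA strategy flags")
        return _VARIANT_FLAGS[self.variant]


@dataclass
class SwarmState:
    """Mutable state of one optimizer run."""

    positions: np.ndarray
    fitness: np.ndarray
    velocities: np.ndarray
    pbest_positions: np.ndarray
    pbest_fitness: np.ndarray
    gbest_position: np.ndarray
    gbest_fitness: float
    iter: int = 0


@dataclass
class OptimizationResult:
    best_position: np.ndarray
    best_fitness: float
    history: np.ndarray
    n_evaluations: int


def initialize_population(
    space: SearchSpace, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Uniform positions x_ij = (ub_j - lb_j) * r + lb_j, fresh r per entry."""
    if n < 2:
        raise ValueError("population size must be >= 2")
    r = rng.random((n, space.dim))
    return (space.ub - space.lb) * r + space.lb


def _make_state(problem: ObjectiveProblem, n: int, rng: np.random.Generator) -> SwarmState:
    x = initialize_population(problem.space, n, rng)
    f = evaluate_batch(problem, x)
    best = int(np.argmin(f))
    return SwarmState(
        positions=x,
        fitness=f,
        velocities=np.zeros_like(x),
        pbest_positions=x.copy(),
        pbest_fitness=f.copy(),
        gbest_position=x[best].copy(),
        gbest_fitness=float(f[best]),
    )


_LEVY_ETA = 1.5


def _levy_sigma(eta: float = _LEVY_ETA) -> float:
    from scipy.special import gamma

    return (
        gamma(1.0 + eta)
        * np.sin(np.pi * eta / 2.0)
        / (gamma((1.0 + eta) / 2.0) * eta * 2.0 ** ((eta - 1.0) / 2.0))
    ) ** (1.0 / eta)


_SIGMA = _levy_sigma()


def levy_flight(dim: int, rng: np.random.Generator, size: Optional[int] = None) -> np.ndarray:
    """Damped Lévy step RL = 0.5 * 0.01 * u*sigma / |v|^(1/eta), eta = 1.5.

    ``u`` and ``v`` are standard-normal (Mantegna's algorithm; the sigma
    constant is Mantegna's closed form).  Draw order: all of ``u`` first,
    then all of ``v``.  With ``size`` given, returns a (size, dim) matrix.
    """
    shape = (dim,) if size is None else (size, dim)
    u = rng.standard_normal(shape)
    v = rng.standard_normal(shape)
    return 0.5 * 0.01 * u * _SIGMA / np.abs(v) ** (1.0 / _LEVY_ETA)


def hunting_stage(iteration: int, t_max: int) -> int:
    """Stage index 1/2/3: iter <= T/3, T/3 < iter <= 2T/3, else 3."""
    if iteration <= t_max / 3.0:
        return 1
    if iteration <= 2.0 * t_max / 3.0:
        return 2
    return 3


def _pick_two_peers(n: int, i: int, rng: np.random.Generator) -> tuple[int, int]:
    # two independent uniform picks among the other individuals (may coincide)
    a = int(rng.integers(0, n - 1))
    b = int(rng.integers(0, n - 1))
    return a + (a >= i), b + (b >= i)


def _hunting_p1(state: SwarmState, rng: np.random.Generator) -> np.ndarray:
    """Prey search: x_i + r2 * (x_r1 - x_r2), fresh U(0,1) r2 per entry.

    Draw order per individual: peer index r1, peer index r2, then the D
    uniforms of r2.
    """
    n, d = state.positions.shape
    out = np.empty_like(state.positions)
    for i in range(n):
        a, b = _pick_two_peers(n, i, rng)
        r2 = rng.random(d)
        out[i] = state.positions[i] + r2 * (state.positions[a] - state.positions[b])
    return out


def _hunting_p2(state: SwarmState, iteration: int, t_max: int, rng: np.random.Generator) -> np.ndarray:
    """Prey exhaustion: x_best + exp((iter/T)^4) * (RB - 0.5) * (x_best - x_i)."""
    rb = rng.standard_normal(state.positions.shape)
    scale = np.exp((iteration / t_max) ** 4)
    return state.gbest_position + scale * (rb - 0.5) * (state.gbest_position - state.positions)


def _hunting_p3(state: SwarmState, iteration: int, t_max: int, rng: np.random.Generator) -> np.ndarray:
    """Attack: x_best + (1 - iter/T)^(2*iter/T) * x_i * RL, fresh Lévy row per individual."""
    n, d = state.positions.shape
    rl = levy_flight(d, rng, size=n)
    damp = (1.0 - iteration / t_max) ** (2.0 * iteration / t_max)
    return state.gbest_position + damp * state.positions * rl


def hunting_update_sboa(
    state: SwarmState, iteration: int, t_max: int, rng: np.random.Generator
) -> np.ndarray:
    """Base three-stage hunting proposal matrix."""
    stage = hunting_stage(iteration, t_max)
    if stage == 1:
        return _hunting_p1(state, rng)
    if stage == 2:
        return _hunting_p2(state, iteration, t_max, rng)
    return _hunting_p3(state, iteration, t_max, rng)


def escape_update(
    state: SwarmState, iteration: int, t_max: int, rng: np.random.Generator, q: float = 0.5
) -> np.ndarray:
    """Two-branch escape proposals.

    One scalar U(0,1) draw per individual decides the branch against
    ``q = 0.5``: S1 (flee toward the best solution, damped by
    (1 - iter/T)^2) or S2 (camouflage toward a random peer).  To keep the
    stream layout independent of the branch pattern, the draws for both
    branches are consumed for every individual, in the order: branch
    uniforms (N), RB normals (N x D), r4 uniforms (N x D), peer indices (N),
    l coefficients (N).
    """
    n, d = state.positions.shape
    branch = rng.random(n) < q  # True -> S1
    rb = rng.standard_normal((n, d))
    r4 = rng.random((n, d))
    peers = rng.integers(0, n - 1, size=n)
    peers = peers + (peers >= np.arange(n))
    l = rng.integers(1, 3, size=n).astype(float)

    damp = (1.0 - iteration / t_max) ** 2
    s1 = state.gbest_position + (2.0 * rb - 1.0) * damp * state.positions
    s2 = state.positions + r4 * (
        state.positions[peers] - l[:, None] * state.positions
    )
    return np.where(branch[:, None], s1, s2)


def greedy_select(
    state: SwarmState, proposals: np.ndarray, proposal_fitness: np.ndarray
) -> SwarmState:
    """Replace individual i iff its proposal fitness is strictly lower.

    Ties keep the incumbent.  Personal and global bests are refreshed
    in place.
    """
    improved = proposal_fitness < state.fitness
    state.positions[improved] = proposals[improved]
    state.fitness[improved] = proposal_fitness[improved]
    state.pbest_positions[improved] = proposals[improved]
    state.pbest_fitness[improved] = proposal_fitness[improved]
    best = int(np.argmin(state.fitness))
    if state.fitness[best] < state.gbest_fitness:
        state.gbest_fitness = float(state.fitness[best])
        state.gbest_position = state.positions[best].copy()
    return state


def clip_to_bounds(positions: np.ndarray, space: SearchSpace) -> np.ndarray:
    """Clamp each entry into [lb_j, ub_j]."""
    return np.clip(positions, space.lb, space.ub)


def run_sboa(problem: ObjectiveProblem, config: OptimizerConfig) -> OptimizationResult:
    """Base SBOA: all enhancement strategies disabled."""
    from ._engine import run_engine

    return run_engine(problem, config, use_pso=False, use_boundary=False, use_quantum=False)


def run_reference_pso(problem: ObjectiveProblem, config: OptimizerConfig) -> OptimizationResult:
    """Global-best PSO comparator with w=0.9, c1=c2=1.49445.

    Draw order per iteration: r1 uniforms (N x D), then r2 uniforms (N x D).
    Positions are clipped to the box; one evaluation per particle per
    iteration; personal/global bests accept ties in favour of the incumbent.
    """
    w, c1, c2 = 0.9, 1.49445, 1.49445
    rng = np.random.default_rng(config.seed)
    state = _make_state(problem, config.pop_size, rng)
    n_evals = config.pop_size
    history = np.empty(config.max_iter)
    for it in range(1, config.max_iter + 1):
        r1 = rng.random(state.positions.shape)
        r2 = rng.random(state.positions.shape)
        state.velocities = (
            w * state.velocities
            + c1 * r1 * (state.pbest_positions - state.positions)
            + c2 * r2 * (state.gbest_position - state.positions)
        )
        state.positions = clip_to_bounds(state.positions + state.velocities, problem.space)
        state.fitness = evaluate_batch(problem, state.positions)
        n_evals += config.pop_size
        improved = state.fitness < state.pbest_fitness
        state.pbest_positions[improved] = state.positions[improved]
        state.pbest_fitness[improved] = state.fitness[improved]
        best = int(np.argmin(state.pbest_fitness))
        if state.pbest_fitness[best] < state.gbest_fitness:
            state.gbest_fitness = float(state.pbest_fitness[best])
            state.gbest_position = state.pbest_positions[best].copy()
        history[it - 1] = state.gbest_fitness
    return OptimizationResult(
        best_position=state.gbest_position.copy(),
        best_fitness=float(state.gbest_fitness),
        history=history,
        n_evaluations=n_evals,
    )
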