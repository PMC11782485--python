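"""Enhancement strategies for SBOA and the assembled QHSBOA optimizer.

Three independent strategies augment the base secretary-bird algorithm:

1. **PSO search mechanism** — the middle hunting stage is replaced by a
   particle-swarm velocity update with linearly decaying inertia
   ``w = 1 - iter/T``, re-using each individual's personal best and the
   global best as attractors.
2. **Dynamic boundary repair** — out-of-box entries are pulled to the
   midpoint between the violated bound and the corresponding entry of the
   best individual, instead of being clamped to the bound.
3. **Quantum-rotation t-distribution mutation** — once per iteration the
   global best is perturbed along qubit-amplitude directions (angles on the
   unit circle, optionally rotated by a shared angle, scaled by the norm of
   the best solution) with Student-t step sizes whose degrees of freedom
   equal the iteration number, so steps are heavy-tailed early and
   near-Gaussian late; a candidate replaces the best only on strict
   improvement (elite selection).

Enabling exactly one strategy gives the ablation variants PSBOA, DSBOA and
QSBOA; all three give QHSBOA; none reproduces base SBOA bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import partial
from typing import Callable, Tuple

import numpy as np

from .problems import ObjectiveProblem, SearchSpace, evaluate_batch
from .sboa import (
    OptimizationResult,
    OptimizerConfig,
    SwarmState,
    hunting_stage,
    _hunting_p1,
    _hunting_p3,
)

__all__ = [
    "QuantumMutationDraw",
    "pso_velocity_update",
    "hunting_update_qhsboa",
    "dynamic_boundary_repair",
    "sample_t_factor",
    "quantum_t_mutation",
    "run_qhsboa",
    "make_variant",
]


@dataclass(frozen=True)
class QuantumMutationDraw:
    """Random quantities of one quantum mutation call (for inspection/tests).

    ``alpha``/``beta`` are the qubit amplitudes cos(phi_j)/sin(phi_j), which
    satisfy alpha_j^2 + beta_j^2 = 1; ``theta`` is the shared rotation
    angle; ``signs`` holds the four per-candidate Rademacher sign vectors;
    ``t_scale`` the four per-candidate t-distributed step vectors.
    """

    alpha: np.ndarray
    beta: np.ndarray
    theta: float
    signs: np.ndarray
    t_scale: np.ndarray


def pso_velocity_update(
    state: SwarmState,
    iteration: int,
    t_max: int,
    c1: float,
    c2: float,
    rng: np.random.Generator,
) -> Tuple[np.ndarray, np.ndarray]:
    """v <- w*v + c1*a1*(pbest - x) + c2*a2*(gbest - x); proposal = x + v.

    ``w = 1 - iter/T``; a1, a2 fresh U(0,1) per entry (a1 matrix drawn
    first).  Returns (new velocities, proposals) without mutating state.
    """
    w = 1.0 - iteration / t_max
    a1 = rng.random(state.positions.shape)
    a2 = rng.random(state.positions.shape)
    v = (
        w * state.velocities
        + c1 * a1 * (state.pbest_positions - state.positions)
        + c2 * a2 * (state.gbest_position - state.positions)
    )
    return v, state.positions + v


def hunting_update_qhsboa(
    state: SwarmState,
    iteration: int,
    t_max: int,
    config: OptimizerConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Hunting proposals with the PSO mechanism in the middle stage.

    Stages 1 and 3 are identical to base SBOA; stage 2 performs the PSO
    velocity update (velocities are stored back into the state).
    """
    stage = hunting_stage(iteration, t_max)
    if stage == 1:
        return _hunting_p1(state, rng)
    if stage == 2:
        v, proposals = pso_velocity_update(state, iteration, t_max, config.c1, config.c2, rng)
        state.velocities = v
        return proposals
    return _hunting_p3(state, iteration, t_max, rng)


def dynamic_boundary_repair(
    positions: np.ndarray, anchor_positions: np.ndarray, space: SearchSpace
) -> np.ndarray:
    """Repair out-of-box entries toward the anchor (best) individual.

    Entries above ``ub_j`` become ``(anchor_ij + ub_j)/2``; entries below
    ``lb_j`` become ``(anchor_ij + lb_j)/2``; in-box entries are untouched.
    With in-box anchors the result is always in-box (midpoint of two box
    points).  ``anchor_positions`` broadcasts, so a single best row may
    anchor the whole population.
    """
    anchor = np.broadcast_to(anchor_positions, positions.shape)
    out = np.where(positions > space.ub, (anchor + space.ub) / 2.0, positions)
    out = np.where(positions < space.lb, (anchor + space.lb) / 2.0, out)
    return out


def sample_t_factor(df: float, rng: np.random.Generator, size=None):
    """Student-t draw(s) with ``df`` degrees of freedom."""
    if df <= 0:
        raise ValueError(f"degrees of freedom must be positive, got {df}")
    return rng.standard_t(df, size=size)


def quantum_t_mutation(
    gbest_position: np.ndarray,
    gbest_fitness: float,
    iteration: int,
    problem: ObjectiveProblem,
    rng: np.random.Generator,
    return_draw: bool = False,
):
    """Quantum-rotation t-mutation of the global best with elite selection.

    Per-dimension angles phi_j ~ U[0, 2pi) define amplitudes
    (alpha_j, beta_j) = (cos phi_j, sin phi_j); one shared rotation angle
    theta ~ U[0, 2pi] maps them to (alpha', beta') through the planar
    rotation matrix.  The four amplitude vectors alpha, beta, alpha', beta'
    are scaled back to solution space by ||x_best|| (Euclidean norm) with an
    independent Rademacher sign per dimension per candidate, then applied as
    ``x_best + t * direction`` with a fresh Student-t factor per dimension
    per candidate (degrees of freedom = ``iteration``).  The best of the
    four candidates replaces the incumbent only on strict improvement.

    Draw order: phi (D), theta (1), then per candidate k = 1..4: signs (D),
    t factors (D); the four candidates are clipped to the box and evaluated
    in one batch.  Returns (position, fitness) — or
    (position, fitness, QuantumMutationDraw) when ``return_draw`` is set.
    """
    if iteration < 1:
        raise ValueError("iteration must be >= 1")
    x_best = np.asarray(gbest_position, dtype=float)
    d = x_best.size
    phi = rng.random(d) * 2.0 * np.pi
    alpha, beta = np.cos(phi), np.sin(phi)
    theta = float(rng.random() * 2.0 * np.pi)
    alpha_rot = np.cos(theta) * alpha - np.sin(theta) * beta
    beta_rot = np.sin(theta) * alpha + np.cos(theta) * beta
    norm = float(np.linalg.norm(x_best))

    amplitudes = (alpha, beta, alpha_rot, beta_rot)
    signs = np.empty((4, d))
    t_scale = np.empty((4, d))
    candidates = np.empty((4, d))
    for k, amp in enumerate(amplitudes):
        signs[k] = np.where(rng.random(d) < 0.5, 1.0, -1.0)
        t_scale[k] = sample_t_factor(iteration, rng, size=d)
        candidates[k] = x_best + t_scale[k] * (signs[k] * amp * norm)

    # heavy-tailed t steps can leave the box; the best solution must stay feasible
    candidates = np.clip(candidates, problem.space.lb, problem.space.ub)
    cand_fitness = evaluate_batch(problem, candidates)
    k_best = int(np.argmin(cand_fitness))
    if cand_fitness[k_best] < gbest_fitness:
        pos, fit = candidates[k_best].copy(), float(cand_fitness[k_best])
    else:
        pos, fit = x_best.copy(), float(gbest_fitness)
    if return_draw:
        return pos, fit, QuantumMutationDraw(alpha, beta, theta, signs, t_scale)
    return pos, fit


def run_qhsboa(problem: ObjectiveProblem, config: OptimizerConfig) -> OptimizationResult:
    """Run the optimizer with the strategies selected by ``config.variant``."""
    from ._engine import run_engine

    use_pso, use_boundary, use_quantum = config.strategy_flags()
    return run_engine(
        problem, config, use_pso=use_pso, use_boundary=use_boundary, use_quantum=use_quantum
    )


def make_variant(variant_name: str) -> Callable[[ObjectiveProblem, OptimizerConfig], OptimizationResult]:
    """Optimizer callable for one ablation variant (PSBOA/DSBOA/QSBOA/QHSBOA/SBOA).

    The returned callable overrides ``config.variant`` with the requested
    one, so a shared config can drive paired comparisons.
    """
    name = variant_name.upper()
    if name == "PSO":
        from .sboa import run_reference_pso

        return run_reference_pso
    if name not in ("SBOA", "PSBOA", "DSBOA", "QSBOA", "QHSBOA"):
        raise ValueError(f"unknown variant {variant_name!r}")

    def runner(problem: ObjectiveProblem, config: OptimizerConfig, _name=name):
        return run_qhsboa(problem, replace(config, variant=_name))

    runner.__name__ = f"run_{name.lower()}"
    return runner
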