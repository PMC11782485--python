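"""Shared iteration engine for SBOA and its enhanced variants.

One loop serves base SBOA and every strategy combination, so that
disabling all strategies reproduces the base algorithm bit-exactly from
the same seed (identical code path, identical draw order).

Per-iteration structure (iterations counted 1..T):

1. hunting proposals (three-stage; PSO velocity update in the middle
   stage when enabled) -> repair -> evaluate -> greedy accept/reject
2. escape proposals (two-branch) -> repair -> evaluate -> greedy
   accept/reject
3. when the quantum strategy is enabled: one quantum t-mutation of the
   global best (four candidate evaluations, elite selection)
4. record the global best fitness

Evaluation budget: N at initialization, then 2N per iteration, plus 4 per
iteration with the quantum strategy.
"""

from __future__ import annotations

import numpy as np

from .problems import ObjectiveProblem, evaluate_batch
from .qhsboa import dynamic_boundary_repair, hunting_update_qhsboa, quantum_t_mutation
from .sboa import (
    OptimizationResult,
    OptimizerConfig,
    _make_state,
    clip_to_bounds,
    escape_update,
    greedy_select,
    hunting_update_sboa,
)


def run_engine(
    problem: ObjectiveProblem,
    config: OptimizerConfig,
    *,
    use_pso: bool,
    use_boundary: bool,
    use_quantum: bool,
) -> OptimizationResult:
    rng = np.random.default_rng(config.seed)
    evals_before = problem.n_evaluations
    state = _make_state(problem, config.pop_size, rng)
    space = problem.space
    history = np.empty(config.max_iter)

    def repair(proposals: np.ndarray) -> np.ndarray:
        if not use_boundary:
            return clip_to_bounds(proposals, space)
        anchor = (
            state.pbest_positions
            if config.boundary_anchor == "pbest"
            else state.gbest_position
        )
        return dynamic_boundary_repair(proposals, anchor, space)

    for it in range(1, config.max_iter + 1):
        state.iter = it
        if use_pso:
            proposals = hunting_update_qhsboa(state, it, config.max_iter, config, rng)
        else:
            proposals = hunting_update_sboa(state, it, config.max_iter, rng)
        proposals = repair(proposals)
        greedy_select(state, proposals, evaluate_batch(problem, proposals))

        proposals = repair(escape_update(state, it, config.max_iter, rng))
        greedy_select(state, proposals, evaluate_batch(problem, proposals))

        if use_quantum:
            state.gbest_position, state.gbest_fitness = quantum_t_mutation(
                state.gbest_position, state.gbest_fitness, it, problem, rng
            )
        history[it - 1] = state.gbest_fitness

    return OptimizationResult(
        best_position=state.gbest_position.copy(),
        best_fitness=float(state.gbest_fitness),
        history=history,
        n_evaluations=problem.n_evaluations - evals_before,
    )
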