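"""Multi-run benchmarking harness and nonparametric comparison statistics.

Benchmark runs are paired across algorithms by common random numbers
(seed = base_seed + run_index), summarized into mean / standard deviation
/ per-problem rank tables, and compared with the two-sided Wilcoxon
rank-sum test (exact by enumeration for small samples, normal
approximation with tie and continuity corrections otherwise) and Friedman
mean ranks across problems.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Callable, Dict, List, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm, rankdata

from .problems import ObjectiveProblem
from .sboa import OptimizationResult, OptimizerConfig

__all__ = [
    "RunRecord",
    "run_experiment",
    "summarize",
    "wilcoxon_rank_sum",
    "significance_table",
    "export_convergence",
    "friedman_statistic",
]

#: exact enumeration is used up to this pooled sample size
_EXACT_LIMIT = 12


@dataclass
class RunRecord:
    algorithm: str
    problem: str
    run_index: int
    final_fitness: float
    history: np.ndarray
    seed: int


def run_experiment(
    problems: Sequence[ObjectiveProblem],
    algorithms: Dict[str, Callable[[ObjectiveProblem, OptimizerConfig], OptimizationResult]],
    runs: int,
    base_seed: int,
    config: OptimizerConfig | None = None,
) -> List[RunRecord]:
    """Run every algorithm on every problem ``runs`` times with paired seeds.

    Seeds are ``base_seed + run_index``, identical across algorithms, so
    cross-algorithm comparisons use common random numbers.
    """
    if runs < 1:
        raise ValueError("runs must be >= 1")
    base_config = config or OptimizerConfig()
    records: List[RunRecord] = []
    for problem in problems:
        for name, algorithm in algorithms.items():
            for r in range(runs):
                seed = base_seed + r
                cfg = OptimizerConfig(
                    pop_size=base_config.pop_size,
                    max_iter=base_config.max_iter,
                    seed=seed,
                    variant=base_config.variant,
                    c1=base_config.c1,
                    c2=base_config.c2,
                    boundary_anchor=base_config.boundary_anchor,
                )
                try:
                    result = algorithm(problem, cfg)
                except Exception as err:
                    raise RuntimeError(
                        f"optimizer {name!r} failed on {problem.name!r} run {r}"
                    ) from err
                records.append(
                    RunRecord(
                        algorithm=name,
                        problem=problem.name,
                        run_index=r,
                        final_fitness=float(result.best_fitness),
                        history=np.asarray(result.history),
                        seed=seed,
                    )
                )
    return records


def summarize(records: Sequence[RunRecord]) -> pd.DataFrame:
    """Ave/Std/Rank table per (problem, algorithm) plus Friedman mean ranks.

    Ave is the sample mean of final fitness, Std the n-1 standard
    deviation, Rank the per-problem rank of Ave (ascending, average ranks
    on ties).  ``mean_rank`` averages an algorithm's ranks over problems
    (the Friedman mean rank); ``friedman_rank`` orders algorithms by it.
    Requires a complete design.
    """
    df = pd.DataFrame(
        {
            "problem": [r.problem for r in records],
            "algorithm": [r.algorithm for r in records],
            "final_fitness": [r.final_fitness for r in records],
        }
    )
    counts = df.groupby(["problem", "algorithm"]).size()
    algorithm_sets = {
        problem: tuple(sorted(grp.index.get_level_values("algorithm")))
        for problem, grp in counts.groupby("problem")
    }
    if counts.nunique() != 1 or len(set(algorithm_sets.values())) != 1:
        raise ValueError("incomplete design: every algorithm must run every problem equally often")
    table = (
        df.groupby(["problem", "algorithm"])["final_fitness"]
        .agg(ave="mean", std=lambda s: s.std(ddof=1))
        .reset_index()
    )
    table["rank"] = table.groupby("problem")["ave"].transform(
        lambda s: rankdata(s, method="average")
    )
    mean_ranks = table.groupby("algorithm")["rank"].mean().rename("mean_rank")
    table = table.merge(mean_ranks, on="algorithm")
    order = rankdata(mean_ranks.values, method="average")
    table = table.merge(
        pd.Series(order, index=mean_ranks.index, name="friedman_rank"), on="algorithm"
    )
    return table.sort_values(["problem", "algorithm"]).reset_index(drop=True)


def friedman_statistic(records: Sequence[RunRecord]) -> dict:
    """Friedman chi-square over the per-problem ranks of Ave, with p-value."""
    table = summarize(records)
    mean_ranks = table.groupby("algorithm")["mean_rank"].first()
    k = mean_ranks.size
    n_problems = table["problem"].nunique()
    stat = (
        12.0 * n_problems / (k * (k + 1)) * float(np.sum((mean_ranks.values - (k + 1) / 2.0) ** 2))
    )
    p = float(chi2.sf(stat, df=k - 1)) if k > 1 else 1.0
    return {"statistic": stat, "p_value": p, "mean_ranks": mean_ranks.to_dict()}


def _exact_rank_sum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Conditional permutation p: enumerate all splits of the pooled midranks.

    The null distribution of the rank sum of sample ``a`` is symmetric
    about n1(N+1)/2 (midrank multisets are symmetric under r -> N+1-r), so
    the two-sided p counts splits at least as far from that center as the
    observed sum.
    """
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled, method="average")
    n1, n_total = a.size, pooled.size
    observed = float(np.sum(ranks[:n1]))
    center = n1 * (n_total + 1) / 2.0
    obs_dev = abs(observed - center)
    count = 0
    total = 0
    for subset in itertools.combinations(range(n_total), n1):
        total += 1
        w = float(np.sum(ranks[list(subset)]))
        if abs(w - center) >= obs_dev - 1e-12:
            count += 1
    return count / total


def _approx_rank_sum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Normal approximation with tie correction and continuity correction."""
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled, method="average")
    n1, n2 = a.size, b.size
    n_total = n1 + n2
    w = float(np.sum(ranks[:n1]))
    mu = n1 * (n_total + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (n_total * (n_total - 1))
    var = n1 * n2 / 12.0 * ((n_total + 1) - tie_term)
    if var <= 0:
        return 1.0
    z = (abs(w - mu) - 0.5) / math.sqrt(var)
    z = max(z, 0.0)
    return float(2.0 * norm.sf(z))


def wilcoxon_rank_sum(a, b) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact enumeration of the conditional permutation distribution for
    pooled sizes up to 12; tie- and continuity-corrected normal
    approximation beyond that.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if a.size + b.size <= _EXACT_LIMIT:
        return _exact_rank_sum_p(a, b)
    return _approx_rank_sum_p(a, b)


def significance_table(
    records: Sequence[RunRecord], reference_algorithm: str, alpha: float = 0.05
) -> pd.DataFrame:
    """Reference-vs-other rank-sum p per problem, flagged at the 5% level."""
    algorithms = sorted({r.algorithm for r in records})
    if reference_algorithm not in algorithms:
        raise ValueError(f"reference algorithm {reference_algorithm!r} not in records")
    by_key: Dict[tuple, List[float]] = {}
    for r in records:
        by_key.setdefault((r.problem, r.algorithm), []).append(r.final_fitness)
    rows = []
    for problem in sorted({r.problem for r in records}):
        ref = by_key[(problem, reference_algorithm)]
        for algorithm in algorithms:
            p = 1.0 if algorithm == reference_algorithm else wilcoxon_rank_sum(
                ref, by_key[(problem, algorithm)]
            )
            rows.append(
                {
                    "problem": problem,
                    "algorithm": algorithm,
                    "p_value": p,
                    "significant": bool(p <= alpha) and algorithm != reference_algorithm,
                }
            )
    return pd.DataFrame(rows)


def export_convergence(records: Sequence[RunRecord], path) -> None:
    """Long-format CSV: algorithm, problem, run, iteration, best_fitness."""
    frames = []
    for r in records:
        frames.append(
            pd.DataFrame(
                {
                    "algorithm": r.algorithm,
                    "problem": r.problem,
                    "run": r.run_index,
                    "iteration": np.arange(1, r.history.size + 1),
                    "best_fitness": r.history,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
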