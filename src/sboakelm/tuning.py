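"""Hyperparameter tuning of KELM by swarm search, with nested cross-validation.

The classifier has two hyperparameters — penalty C and kernel width c —
searched over the box [1, 20]^2.  The tuning objective is
``1 - avgAcc``, where avgAcc is the mean held-out accuracy over k
stratified inner folds (optimizers minimize; the protocol maximizes
accuracy).  Generalization is estimated by nested cross-validation:
for each outer fold, hyperparameters are tuned on the outer-training
portion only (inner folds, default 5), the model is refit on the full
outer-training portion with the tuned (C, c), and scored on the held-out
fold; the procedure is repeated over freshly drawn outer folds and
averaged.  All preprocessing statistics (imputation means, min-max
ranges) are fit on training portions only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .kelm import kelm_predict, kelm_train
from .problems import ObjectiveProblem, SearchSpace
from .qhsboa import run_qhsboa
from .sboa import OptimizationResult, OptimizerConfig
from .synthetic_data import impute_mean, minmax_normalize

__all__ = [
    "TuningConfig",
    "ClassificationMetrics",
    "NestedCVResult",
    "stratified_kfold_indices",
    "compute_metrics",
    "cv_fitness",
    "tune_kelm",
    "nested_cv_evaluate",
]


@dataclass
class TuningConfig:
    """Protocol configuration for tuning and nested evaluation.

    Defaults follow the study protocol: search box [1, 20]^2, 5 inner
    folds for tuning, 10 outer folds and 30 repeats for evaluation.  The
    optimizer budget inside tuning defaults to a desk-scale population of
    20 and 30 iterations (both configurable).
    """

    C_range: Tuple[float, float] = (1.0, 20.0)
    c_range: Tuple[float, float] = (1.0, 20.0)
    inner_folds: int = 5
    outer_folds: int = 10
    repeats: int = 30
    optimizer: OptimizerConfig = field(
        default_factory=lambda: OptimizerConfig(pop_size=20, max_iter=30, variant="QHSBOA")
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for lo, hi in (self.C_range, self.c_range):
            if hi < lo:
                raise ValueError("parameter ranges must have non-negative width")
        if self.inner_folds < 2 or self.outer_folds < 2:
            raise ValueError("fold counts must be >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


@dataclass
class ClassificationMetrics:
    """ACC/sensitivity/specificity/F1/recall in percent; MCC dimensionless."""

    acc: float
    mcc: float
    sensitivity: float
    specificity: float
    f1: float
    recall: float

    def as_dict(self) -> dict:
        return asdict(self)


def stratified_kfold_indices(
    y: np.ndarray, k: int, rng: np.random.Generator
) -> List[np.ndarray]:
    """k disjoint index sets with per-class counts within +/-1 of proportional.

    Each class's shuffled indices are split into k nearly equal chunks and
    the chunk-size ordering is rotated per class so no fold systematically
    collects all the remainders.
    """
    y = np.asarray(y)
    if k < 2:
        raise ValueError("k must be >= 2")
    classes, counts = np.unique(y, return_counts=True)
    small = classes[counts < k]
    if small.size:
        raise ValueError(f"classes {small.tolist()} have fewer than k={k} members")
    folds: List[List[int]] = [[] for _ in range(k)]
    for offset, cls in enumerate(classes):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        chunks = np.array_split(idx, k)
        for j, chunk in enumerate(chunks):
            folds[(j + offset) % k].extend(chunk.tolist())
    return [np.sort(np.asarray(f, dtype=int)) for f in folds]


def _confusion(y_true: np.ndarray, y_pred: np.ndarray, positive) -> Tuple[int, int, int, int]:
    t_pos = y_true == positive
    p_pos = y_pred == positive
    tp = int(np.sum(t_pos & p_pos))
    tn = int(np.sum(~t_pos & ~p_pos))
    fp = int(np.sum(~t_pos & p_pos))
    fn = int(np.sum(t_pos & ~p_pos))
    return tp, tn, fp, fn


def compute_metrics(y_true, y_pred, positive_label=1) -> ClassificationMetrics:
    """Confusion-count metrics with the positive class = diseased (label 1).

    Any metric with a zero denominator (including each factor under the
    MCC square root) is defined as 0.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred have different lengths")
    if y_true.size == 0:
        raise ValueError("need at least one sample")
    tp, tn, fp, fn = _confusion(y_true, y_pred, positive_label)
    n = tp + tn + fp + fn
    acc = 100.0 * (tp + tn) / n
    sens = 100.0 * tp / (tp + fn) if tp + fn else 0.0
    spec = 100.0 * tn / (tn + fp) if tn + fp else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom else 0.0
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall_frac = tp / (tp + fn) if tp + fn else 0.0
    f1 = (
        100.0 * 2.0 * precision * recall_frac / (precision + recall_frac)
        if precision + recall_frac
        else 0.0
    )
    return ClassificationMetrics(
        acc=acc, mcc=float(mcc), sensitivity=sens, specificity=spec, f1=f1, recall=sens
    )


def _fit_predict_fold(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    C: float,
    c: float,
) -> np.ndarray:
    """Preprocess (fit on train), train KELM, predict the test rows.

    A single-class training portion degenerates to the constant classifier.
    """
    X_train, means = impute_mean(X_train)
    X_test, _ = impute_mean(X_test, means)
    X_train, mm = minmax_normalize(X_train)
    X_test, _ = minmax_normalize(X_test, mm)
    if np.unique(y_train).size < 2:
        return np.full(X_test.shape[0], y_train[0])
    model = kelm_train(X_train, y_train, C, c)
    return kelm_predict(model, X_test)


def cv_fitness(
    params: Sequence[float],
    X: np.ndarray,
    y: np.ndarray,
    k: int,
    rng: Optional[np.random.Generator] = None,
    folds: Optional[List[np.ndarray]] = None,
) -> float:
    """Tuning objective 1 - avgAcc over k stratified folds.

    Deterministic given the fold assignment; pass ``folds`` explicitly to
    fix it across objective evaluations (as the tuner does).
    """
    C, c = float(params[0]), float(params[1])
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if folds is None:
        if rng is None:
            raise ValueError("provide either rng or precomputed folds")
        folds = stratified_kfold_indices(y, k, rng)
    accs = []
    all_idx = np.arange(y.size)
    for test_idx in folds:
        train_mask = np.ones(y.size, dtype=bool)
        train_mask[test_idx] = False
        y_pred = _fit_predict_fold(X[train_mask], y[train_mask], X[test_idx], C, c)
        accs.append(float(np.mean(y_pred == y[test_idx])))
    return 1.0 - float(np.mean(accs))


def tune_kelm(
    X: np.ndarray,
    y: np.ndarray,
    config: TuningConfig,
    rng: Optional[np.random.Generator] = None,
    optimizer_seed: Optional[int] = None,
) -> Tuple[float, float, OptimizationResult]:
    """Search (C, c) in the configured box by the enhanced secretary-bird optimizer.

    Inner folds are drawn once and frozen, so the objective seen by the
    optimizer is deterministic.  Returns (best_C, best_c, result).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    folds = stratified_kfold_indices(y, config.inner_folds, rng)
    space = SearchSpace(
        2,
        np.array([config.C_range[0], config.c_range[0]]),
        np.array([config.C_range[1], config.c_range[1]]),
    )
    problem = ObjectiveProblem(
        name="kelm_cv_fitness",
        space=space,
        objective=lambda p: cv_fitness(p, X, y, config.inner_folds, folds=folds),
    )
    opt_config = replace(
        config.optimizer,
        seed=config.optimizer.seed if optimizer_seed is None else optimizer_seed,
    )
    result = run_qhsboa(problem, opt_config)
    return float(result.best_position[0]), float(result.best_position[1]), result


@dataclass
class NestedCVResult:
    """Per-fold records and their aggregate."""

    fold_records: List[dict]
    aggregate: ClassificationMetrics
    tuned_params: List[Tuple[float, float]]

    def metric_matrix(self) -> np.ndarray:
        keys = ("acc", "mcc", "sensitivity", "specificity", "f1", "recall")
        return np.array([[rec["metrics"][k] for k in keys] for rec in self.fold_records])


def nested_cv_evaluate(X: np.ndarray, y: np.ndarray, config: TuningConfig) -> NestedCVResult:
    """Repeated stratified nested cross-validation.

    For each repeat and outer fold: tune (C, c) on the outer-training
    portion (inner folds drawn from the same stream), refit once with the
    tuned parameters on the full outer-training portion, and score the
    held-out fold.  The held-out fold never enters fold construction,
    tuning, preprocessing statistics, or training for its own evaluation.
    The aggregate is the mean over folds, then repeats.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    rng = np.random.default_rng(config.seed)
    records: List[dict] = []
    tuned: List[Tuple[float, float]] = []
    per_repeat_means: List[np.ndarray] = []
    keys = ("acc", "mcc", "sensitivity", "specificity", "f1", "recall")
    for rep in range(config.repeats):
        outer = stratified_kfold_indices(y, config.outer_folds, rng)
        fold_rows = []
        for fold_id, test_idx in enumerate(outer):
            train_mask = np.ones(y.size, dtype=bool)
            train_mask[test_idx] = False
            X_tr, y_tr = X[train_mask], y[train_mask]
            opt_seed = int(rng.integers(2**31))
            best_C, best_c, _ = tune_kelm(X_tr, y_tr, config, rng=rng, optimizer_seed=opt_seed)
            y_pred = _fit_predict_fold(X_tr, y_tr, X[test_idx], best_C, best_c)
            metrics = compute_metrics(y[test_idx], y_pred)
            records.append(
                {
                    "repeat": rep,
                    "fold": fold_id,
                    "test_indices": test_idx.tolist(),
                    "C": best_C,
                    "c": best_c,
                    "metrics": metrics.as_dict(),
                }
            )
            tuned.append((best_C, best_c))
            fold_rows.append([metrics.as_dict()[k] for k in keys])
        per_repeat_means.append(np.mean(np.asarray(fold_rows), axis=0))
    agg = np.mean(np.asarray(per_repeat_means), axis=0)
    aggregate = ClassificationMetrics(**dict(zip(keys, (float(v) for v in agg))))
    return NestedCVResult(fold_records=records, aggregate=aggregate, tuned_params=tuned)
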