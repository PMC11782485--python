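"""Synthetic diabetes-like tabular data and the study's preprocessing.

The generator emulates the *shape* of the Pima Indians Diabetes Dataset —
768 records, 8 numeric features, 268 positive / 500 negative, scattered
missing values — with two Gaussian class-conditional clouds whose
separation is controlled by ``effect_size``.  Half of the features
(rounded up) are informative; the rest are pure noise.  It deliberately
does not copy the real dataset's marginals: the point is a controllable,
reproducible test surface.

Preprocessing mirrors the study protocol: mean imputation of missing
values and min-max normalization to [0, 1], both with fit-on-train /
apply-on-test semantics so cross-validation stays leakage-free.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "TabularDataset",
    "generate_pidd_like",
    "impute_mean",
    "minmax_normalize",
    "read_csv_dataset",
    "write_csv_dataset",
]


@dataclass
class TabularDataset:
    """Feature matrix with binary labels; missing entries are NaN."""

    X: np.ndarray
    y: np.ndarray
    feature_names: list[str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y have different numbers of rows")
        if self.X.ndim != 2 or self.X.shape[1] != len(self.feature_names):
            raise ValueError("feature_names must match the number of columns")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]


def generate_pidd_like(
    n: int = 768,
    n_positive: int = 268,
    d: int = 8,
    effect_size: float = 1.3,
    missing_rate: float = 0.05,
    seed: int = 0,
) -> TabularDataset:
    """Two-cloud Gaussian dataset with exact class counts and MCAR missingness.

    ``ceil(d/2)`` randomly chosen informative features have their
    positive-class mean shifted by ``effect_size`` (unit variance
    throughout); the remaining features are noise.  With the defaults
    (4 informative features, effect 1.3 each) the total class-mean
    separation is 2.6 standard deviations, i.e. a Bayes accuracy of about
    90% under the 500/268 prior.  Missing entries are inserted completely
    at random in feature columns only.
    """
    if not (0 < n_positive < n):
        raise ValueError("need 0 < n_positive < n")
    if not (0 <= missing_rate < 1):
        raise ValueError("missing_rate must be in [0, 1)")
    if d < 1:
        raise ValueError("d must be >= 1")
    rng = np.random.default_rng(seed)
    n_informative = math.ceil(d / 2)
    informative = np.sort(rng.choice(d, size=n_informative, replace=False))
    y = np.zeros(n, dtype=int)
    y[rng.choice(n, size=n_positive, replace=False)] = 1
    X = rng.standard_normal((n, d))
    X[np.ix_(y == 1, informative)] += effect_size
    if missing_rate > 0:
        mask = rng.random((n, d)) < missing_rate
        X[mask] = np.nan
    return TabularDataset(
        X=X,
        y=y,
        feature_names=[f"feature_{j}" for j in range(d)],
        provenance={
            "generator": "pidd_like_gaussian",
            "n": n,
            "n_positive": n_positive,
            "d": d,
            "effect_size": effect_size,
            "missing_rate": missing_rate,
            "seed": seed,
            "informative_features": informative.tolist(),
        },
    )


def _as_matrix(data) -> Tuple[np.ndarray, Optional[TabularDataset]]:
    if isinstance(data, TabularDataset):
        return data.X, data
    return np.atleast_2d(np.asarray(data, dtype=float)), None


def _wrap(matrix: np.ndarray, template: Optional[TabularDataset]):
    if template is None:
        return matrix
    return replace(template, X=matrix)


def impute_mean(data, column_means: Optional[np.ndarray] = None):
    """Replace NaNs by column means; returns (imputed data, means used).

    Supplied ``column_means`` (e.g. fitted on a training split) override
    recomputation so test data can reuse training statistics.  Accepts a
    TabularDataset or a bare matrix and returns the same kind.
    """
    X, template = _as_matrix(data)
    if column_means is None:
        observed = ~np.isnan(X)
        if not observed.any(axis=0).all():
            bad = [j for j in range(X.shape[1]) if not observed[:, j].any()]
            raise ValueError(f"columns {bad} are entirely missing; supply column_means")
        column_means = np.nanmean(X, axis=0)
    else:
        column_means = np.asarray(column_means, dtype=float)
    out = np.where(np.isnan(X), column_means, X)
    return _wrap(out, template), column_means


def minmax_normalize(data, column_min_max: Optional[Tuple[np.ndarray, np.ndarray]] = None):
    """Scale to x' = (x - min)/(max - min); returns (scaled data, (min, max)).

    Fit-on-train / apply-on-test: pass the fitted ``(min, max)`` back in for
    test data.  Constant columns map to 0.  Test values outside the fitted
    range are passed through unclipped (they may fall outside [0, 1]).
    """
    X, template = _as_matrix(data)
    if column_min_max is None:
        lo = np.nanmin(X, axis=0)
        hi = np.nanmax(X, axis=0)
    else:
        lo, hi = (np.asarray(v, dtype=float) for v in column_min_max)
    span = hi - lo
    safe = np.where(span > 0, span, 1.0)
    out = (X - lo) / safe
    out = np.where(span > 0, out, 0.0)
    return _wrap(out, template), (lo, hi)


def write_csv_dataset(data: TabularDataset, path, label_col: str = "Outcome") -> None:
    """Comma-separated, header row, empty cell = missing."""
    df = pd.DataFrame(data.X, columns=data.feature_names)
    df[label_col] = data.y
    # 17 significant digits => float round trip is lossless
    df.to_csv(path, index=False, float_format="%.17g")


def read_csv_dataset(path, label_col: str = "Outcome") -> TabularDataset:
    """Read a CSV with a header row and a 0/1 label column."""
    df = pd.read_csv(path, float_precision="round_trip")
    if label_col not in df.columns:
        raise ValueError(f"label column {label_col!r} not found in {list(df.columns)}")
    y = df[label_col]
    if y.isna().any() or not y.isin([0, 1]).all():
        raise ValueError(f"label column {label_col!r} must contain only 0/1")
    features = [c for c in df.columns if c != label_col]
    return TabularDataset(
        X=df[features].to_numpy(dtype=float),
        y=y.to_numpy(dtype=int),
        feature_names=features,
        provenance={"source": str(path), "label_col": label_col},
    )
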