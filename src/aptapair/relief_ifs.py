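"""Relief feature weighting and incremental feature selection (IFS).

Relief scores each feature by contrasting, for every sampled instance, its
per-feature difference to the nearest same-class neighbors (hits) against the
nearest different-class neighbors (misses):

    W_p <- W_p - diff_p(x, hits)/m + diff_p(x, misses)/m

Per-feature differences are normalized by the feature's range over the data so
weights are comparable across scales; distances between instances are Manhattan
sums of those normalized differences. Defaults follow the common ReliefF
convention (10 neighbors, every instance sampled); ``n_neighbors=1`` gives the
original single-neighbor Relief update.

IFS then evaluates growing prefixes of the weight-ranked feature list with a
caller-supplied cross-validation evaluator and keeps the prefix maximizing
Youden's index (smallest prefix on ties).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError


@dataclass(frozen=True)
class RankedFeatureList:
    """Feature names in descending Relief-weight order."""

    names: tuple[str, ...]
    weights: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if len(self.names) != w.size:
            raise ValidationError("names and weights lengths differ")
        if np.any(np.diff(w) > 1e-12):
            raise ValidationError("weights must be non-increasing")
        object.__setattr__(self, "weights", w)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"rank": np.arange(1, len(self.names) + 1),
             "name": self.names, "weight": self.weights}
        )


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    X = np.asarray(X, dtype=float)
    return X, [f"f{i}" for i in range(X.shape[1])]


def relief_rank(
    X,
    y,
    n_neighbors: int = 10,
    sample_size: int | None = None,
    seed: int = 0,
) -> RankedFeatureList:
    """Rank features by Relief weights.

    X: samples x features (DataFrame or array); y: binary labels. With
    ``sample_size=None`` every instance is used (deterministically, in order);
    otherwise ``sample_size`` instances are drawn without replacement. Constant
    features get weight exactly 0. Ties in weight keep original column order.
    """
    M, names = _as_matrix(X)
    y = np.asarray(y)
    if M.ndim != 2:
        raise ValidationError("X must be 2-D")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValidationError("Relief needs at least two classes in y")
    if np.isnan(M).any():
        raise ValidationError("X contains missing values")
    for c in classes:
        if (y == c).sum() < 2:
            raise ValidationError(f"class {c!r} has fewer than 2 samples")

    n, d = M.shape
    rng_range = M.max(axis=0) - M.min(axis=0)
    safe_range = np.where(rng_range < 1e-12, 1.0, rng_range)
    Z = (M - M.min(axis=0)) / safe_range  # constant cols become constant -> diff 0

    if sample_size is None or sample_size >= n:
        sampled = np.arange(n)
    else:
        sampled = np.sort(np.random.default_rng(seed).choice(n, sample_size, replace=False))
    m = sampled.size

    weights = np.zeros(d)
    for i in sampled:
        diffs = np.abs(Z - Z[i])          # (n, d) normalized per-feature diffs
        dist = diffs.sum(axis=1)          # Manhattan distance
        dist[i] = np.inf                  # never its own neighbor
        same = y == y[i]
        for is_hit in (True, False):
            pool = np.flatnonzero(same if is_hit else ~same)
            order = pool[np.argsort(dist[pool], kind="stable")]
            k = min(n_neighbors, order.size)
            if k == 0:
                continue
            contrib = diffs[order[:k]].mean(axis=0) / m
            weights += -contrib if is_hit else contrib

    order = np.lexsort((np.arange(d), -weights))  # desc weight, ties by column order
    return RankedFeatureList(tuple(names[j] for j in order), weights[order])


@dataclass(frozen=True)
class IFSResult:
    """The IFS curve and the selected prefix."""

    curve: pd.DataFrame  # columns: n_features, youden, sn, sp, acc, mcc
    optimal_n: int
    optimal_features: tuple[str, ...]


def ifs_search(
    ranked: RankedFeatureList,
    X: pd.DataFrame,
    y,
    evaluator: Callable[[pd.DataFrame, np.ndarray, int], "object"],
    step: int = 1,
    seed: int = 0,
) -> IFSResult:
    """Evaluate growing prefixes of the ranked list and keep the Youden-optimal one.

    ``evaluator(X_subset, y, seed)`` must return an object with sn/sp/acc/mcc/
    youden attributes (a mean cross-validated MetricSet). The same fold seed is
    shared across prefixes so curves are comparable. Prefix sizes are
    step, 2*step, ..., plus the full set, i.e. ceil(n/step) evaluations.
    """
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X, dtype=float),
                         columns=[f"f{i}" for i in range(np.asarray(X).shape[1])])
    y = np.asarray(y)
    n_total = len(ranked.names)
    sizes = list(range(step, n_total + 1, step))
    if not sizes or sizes[-1] != n_total:
        sizes.append(n_total)

    records = []
    for n_feat in sizes:
        subset = list(ranked.names[:n_feat])
        metrics = evaluator(X[subset], y, seed)
        records.append({
            "n_features": n_feat,
            "youden": metrics.youden, "sn": metrics.sn, "sp": metrics.sp,
            "acc": metrics.acc, "mcc": metrics.mcc,
        })
    curve = pd.DataFrame.from_records(records)
    best = int(curve["youden"].idxmax())  # idxmax returns the first (smallest n) max
    optimal_n = int(curve.loc[best, "n_features"])
    return IFSResult(curve, optimal_n, tuple(ranked.names[:optimal_n]))
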