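"""Negative-partitioning ensemble random forest for 1:~3 imbalanced pair data.

The majority (negative) class is split into N = floor(n_neg / n_pos) parts;
each part is joined with *all* positives to form a roughly balanced sub-training
set, one random forest is trained per part, and predictions average the base
models' positive-class probabilities (threshold 0.5, ties positive). This uses
every negative example exactly once while keeping each base learner balanced.

Evaluation uses sensitivity, specificity, accuracy, Matthews correlation and
Youden's index J = Sn + Sp - 1, with stratified k-fold cross-validation that
rebuilds the partition ensemble inside every training fold (no leakage).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .errors import ValidationError


@dataclass(frozen=True)
class RFConfig:
    """Base random-forest hyperparameters (the source method leaves them open):
    500 trees, sqrt(d) candidate features per split."""

    n_trees: int = 500
    max_features: str | float = "sqrt"


def _base_seed(seed: int, index: int) -> int:
    """Deterministic per-base-model seed derived from (seed, index)."""
    return int(np.random.SeedSequence([seed, index]).generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class EnsemblePartition:
    """N disjoint negative parts covering all negatives, plus the positive pool."""

    positive_indices: np.ndarray
    negative_parts: tuple[np.ndarray, ...]

    @property
    def n_parts(self) -> int:
        return len(self.negative_parts)

    def subset_indices(self, part: int) -> np.ndarray:
        """Row indices of sub-training set ``part``: all positives + one negative part."""
        return np.concatenate([self.positive_indices, self.negative_parts[part]])


def partition_negatives(y, seed: int = 0) -> EnsemblePartition:
    """Split negatives into N = floor(n_neg / n_pos) shuffled parts of sizes
    differing by at most one. Requires n_neg >= n_pos >= 1."""
    y = np.asarray(y)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    if pos.size < 1:
        raise ValidationError("partitioning requires at least one positive sample")
    if neg.size < pos.size:
        raise ValidationError(
            f"n_neg={neg.size} < n_pos={pos.size}: the negatives are not the "
            "majority class; swap roles or train a single model (N=1)"
        )
    n_parts = neg.size // pos.size
    shuffled = np.random.default_rng(seed).permutation(neg)
    parts = tuple(np.sort(p) for p in np.array_split(shuffled, n_parts))
    return EnsemblePartition(pos, parts)


@dataclass
class EnsembleModel:
    """N trained base forests over identical feature columns."""

    base_models: list[RandomForestClassifier]
    feature_names: tuple[str, ...]
    rf_config: RFConfig
    seed: int

    @property
    def n_parts(self) -> int:
        return len(self.base_models)

    def _check_columns(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            missing = [c for c in self.feature_names if c not in X.columns]
            extra = [c for c in X.columns if c not in self.feature_names]
            if missing or extra:
                raise ValidationError(
                    f"feature columns mismatch; missing={missing[:5]}, extra={extra[:5]}"
                )
            return X[list(self.feature_names)].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.shape[1] != len(self.feature_names):
            raise ValidationError(
                f"expected {len(self.feature_names)} features, got {X.shape[1]}"
            )
        return X

    def predict_proba(self, X) -> np.ndarray:
        """Unweighted mean of the base models' positive-class probabilities."""
        M = self._check_columns(X)
        probs = np.zeros(M.shape[0])
        for model in self.base_models:
            pos_col = int(np.flatnonzero(model.classes_ == 1)[0])
            probs += model.predict_proba(M)[:, pos_col]
        return probs / len(self.base_models)

    def predict(self, X) -> np.ndarray:
        """Positive iff the averaged probability is >= 0.5 (ties positive)."""
        return (self.predict_proba(X) >= 0.5).astype(int)


def train_ensemble(
    X,
    y,
    rf_config: RFConfig | None = None,
    seed: int = 0,
    partition: EnsemblePartition | None = None,
) -> EnsembleModel:
    """Partition the negatives (unless a partition is supplied) and train one
    seeded forest per sub-training set."""
    if rf_config is None:
        rf_config = RFConfig()
    y = np.asarray(y)
    if isinstance(X, pd.DataFrame):
        names = tuple(X.columns)
        M = X.to_numpy(dtype=float)
    else:
        M = np.asarray(X, dtype=float)
        names = tuple(f"f{i}" for i in range(M.shape[1]))
    if partition is None:
        partition = partition_negatives(y, seed=seed)
    models = []
    for part in range(partition.n_parts):
        idx = partition.subset_indices(part)
        if np.unique(y[idx]).size < 2:
            raise ValidationError(f"sub-training set {part} is single-class")
        rf = RandomForestClassifier(
            n_estimators=rf_config.n_trees,
            max_features=rf_config.max_features,
            random_state=_base_seed(seed, part),
            n_jobs=1,
        )
        rf.fit(M[idx], y[idx])
        models.append(rf)
    return EnsembleModel(models, names, rf_config, seed)


def train_single_rf(X, y, rf_config: RFConfig | None = None, seed: int = 0) -> EnsembleModel:
    """A single forest on the full (imbalanced) data, wrapped as a 1-part
    ensemble — the no-ensemble baseline."""
    if rf_config is None:
        rf_config = RFConfig()
    y = np.asarray(y)
    if isinstance(X, pd.DataFrame):
        names, M = tuple(X.columns), X.to_numpy(dtype=float)
    else:
        M = np.asarray(X, dtype=float)
        names = tuple(f"f{i}" for i in range(M.shape[1]))
    rf = RandomForestClassifier(
        n_estimators=rf_config.n_trees,
        max_features=rf_config.max_features,
        random_state=_base_seed(seed, 0),
        n_jobs=1,
    )
    rf.fit(M, y)
    return EnsembleModel([rf], names, rf_config, seed)


# ---------------------------------------------------------------------------
# metrics


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValidationError("confusion counts must be non-negative")


def confusion_counts(y_true, y_pred) -> ConfusionCounts:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    return ConfusionCounts(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


@dataclass(frozen=True)
class MetricSet:
    sn: float
    sp: float
    acc: float
    mcc: float
    youden: float

    def rounded(self, ndigits: int = 3) -> dict[str, float]:
        return {k: round(v, ndigits) for k, v in self.as_dict().items()}

    def as_dict(self) -> dict[str, float]:
        return {"sn": self.sn, "sp": self.sp, "acc": self.acc,
                "mcc": self.mcc, "youden": self.youden}


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"{what} undefined (zero denominator); reporting 0", stacklevel=3)
        return 0.0
    return num / den


def compute_metrics(c: ConfusionCounts) -> MetricSet:
    """Sensitivity, specificity, accuracy, Matthews correlation and Youden's
    J = Sn + Sp - 1 from confusion counts. Undefined ratios report 0 with a
    warning; rounding happens only at reporting time."""
    sn = _safe_div(c.tp, c.tp + c.fn, "sensitivity")
    sp = _safe_div(c.tn, c.tn + c.fp, "specificity")
    acc = _safe_div(c.tp + c.tn, c.tp + c.tn + c.fp + c.fn, "accuracy")
    mcc_den = np.sqrt(
        float(c.tp + c.fn) * (c.tp + c.fp) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    mcc = _safe_div(c.tp * c.tn - c.fp * c.fn, mcc_den, "MCC")
    return MetricSet(sn=sn, sp=sp, acc=acc, mcc=mcc, youden=sn + sp - 1.0)


def mean_metrics(metric_sets: list[MetricSet]) -> MetricSet:
    arr = np.array([[m.sn, m.sp, m.acc, m.mcc, m.youden] for m in metric_sets])
    mean = arr.mean(axis=0)
    return MetricSet(*mean)


@dataclass
class CVResult:
    mean: MetricSet
    per_fold: list[MetricSet]
    pooled: MetricSet


def cross_validate(
    X,
    y,
    k: int = 10,
    rf_config: RFConfig | None = None,
    seed: int = 0,
    strategy: str = "partition-ensemble",
) -> CVResult:
    """Stratified k-fold cross-validation. Within each fold's training portion
    the negative partition and base forests are rebuilt from scratch.

    ``strategy='single'`` trains one forest on the full imbalanced training fold
    (the no-ensemble baseline). The headline result is the fold-average of each
    metric; metrics on pooled confusion counts are also returned.
    """
    if strategy not in ("partition-ensemble", "single"):
        raise ValidationError(f"unknown strategy {strategy!r}")
    y = np.asarray(y)
    if isinstance(X, pd.DataFrame):
        M = X.to_numpy(dtype=float)
        frame = X
    else:
        M = np.asarray(X, dtype=float)
        frame = None
    for c in np.unique(y):
        if (y == c).sum() < k:
            raise ValidationError(
                f"class {c!r} has fewer than k={k} samples; use a smaller k"
            )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % (2**31))
    per_fold = []
    pooled = np.zeros(4, dtype=int)  # tp, fp, tn, fn
    for fold, (train, test) in enumerate(skf.split(M, y)):
        Xtr = frame.iloc[train] if frame is not None else M[train]
        Xte = frame.iloc[test] if frame is not None else M[test]
        fold_seed = _base_seed(seed, fold + 1000)
        if strategy == "partition-ensemble":
            model = train_ensemble(Xtr, y[train], rf_config, seed=fold_seed)
        else:
            model = train_single_rf(Xtr, y[train], rf_config, seed=fold_seed)
        pred = model.predict(Xte)
        c = confusion_counts(y[test], pred)
        per_fold.append(compute_metrics(c))
        pooled += np.array([c.tp, c.fp, c.tn, c.fn])
    pooled_metrics = compute_metrics(ConfusionCounts(*[int(v) for v in pooled]))
    return CVResult(mean=mean_metrics(per_fold), per_fold=per_fold, pooled=pooled_metrics)


# ---------------------------------------------------------------------------
# persistence


def save_model(model: EnsembleModel, out_dir: str | Path) -> None:
    """Persist as a directory: a JSON manifest plus one joblib file per base forest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "n_parts": model.n_parts,
        "feature_names": list(model.feature_names),
        "rf_config": {"n_trees": model.rf_config.n_trees,
                      "max_features": model.rf_config.max_features},
        "seed": model.seed,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    for i, base in enumerate(model.base_models):
        joblib.dump(base, out / f"base_{i}.joblib")


def load_model(model_dir: str | Path) -> EnsembleModel:
    mdir = Path(model_dir)
    manifest = json.loads((mdir / "manifest.json").read_text())
    models = [joblib.load(mdir / f"base_{i}.joblib") for i in range(manifest["n_parts"])]
    cfg = RFConfig(n_trees=manifest["rf_config"]["n_trees"],
                   max_features=manifest["rf_config"]["max_features"])
    return EnsembleModel(models, tuple(manifest["feature_names"]), cfg, manifest["seed"])
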