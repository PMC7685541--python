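"""Random-forest contract layer: fitting, OOB performance, OOB permutation
importance and grid-based hyperparameter tuning.

Tree induction is delegated to scikit-learn; everything the selection
methods rely on — out-of-bag error, percent variance explained, and
unscaled OOB permutation importance (mean decrease accuracy for
classification, MSE increase for regression) — is computed here from the
fitted trees, because scikit-learn's own ``feature_importances_`` is the
impurity measure, which is a different statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

from ._oob import tree_perm_increase_clf, tree_perm_increase_reg
from .simdata import ConfigurationError, DegenerateOutcomeError

__all__ = [
    "ForestSpec",
    "ImportanceVector",
    "ModelPerformance",
    "FittedForest",
    "fit_forest",
    "tune_hyperparameters",
    "default_tuning_grid",
]


@dataclass(frozen=True)
class ForestSpec:
    """Forest hyperparameters.

    ``mtry=None`` resolves at fit time to ``floor(sqrt(p))`` for
    classification and ``max(floor(p/3), 1)`` for regression;
    ``min_node_size=None`` resolves to 1 / 5 respectively (the
    conventional forest defaults for each task).
    """

    task: str = "regression"
    n_trees: int = 500
    mtry: Optional[int] = None
    min_node_size: Optional[int] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.task not in ("regression", "classification"):
            raise ConfigurationError(f"unknown task {self.task!r}")
        if self.n_trees < 1:
            raise ConfigurationError("n_trees must be >= 1")
        if self.mtry is not None and self.mtry < 1:
            raise ConfigurationError("mtry must be >= 1")

    def resolve(self, p: int) -> "ForestSpec":
        """Fill in data-dependent defaults for a problem with ``p`` features."""
        mtry = self.mtry
        if mtry is None:
            mtry = int(np.sqrt(p)) if self.task == "classification" else max(p // 3, 1)
        mtry = max(1, min(mtry, p))
        mns = self.min_node_size
        if mns is None:
            mns = 1 if self.task == "classification" else 5
        return replace(self, mtry=mtry, min_node_size=mns)


@dataclass
class ImportanceVector:
    """Per-variable importance scores and the implied ranking.

    Ranking is by score descending with ties broken by variable index
    ascending, so it is a deterministic, complete permutation.
    """

    scores: np.ndarray
    ranking: np.ndarray
    names: Optional[Sequence[str]] = None

    @classmethod
    def from_scores(cls, scores: np.ndarray, names=None) -> "ImportanceVector":
        scores = np.asarray(scores, dtype=float)
        order = np.lexsort((np.arange(scores.size), -scores))
        return cls(scores=scores, ranking=order, names=names)

    def top(self, k: int) -> np.ndarray:
        return self.ranking[:k]


@dataclass
class ModelPerformance:
    """OOB performance summary.

    For classification ``oob_error`` is the OOB misclassification
    fraction; for regression ``oob_mse`` and ``pct_var_explained``
    (``100·(1 − OOB MSE / Var(y))``, which can be negative for models
    worse than the mean predictor).
    """

    task: str
    oob_error: Optional[float] = None
    oob_mse: Optional[float] = None
    pct_var_explained: Optional[float] = None

    @property
    def loss(self) -> float:
        """Scalar to minimise: class error or MSE depending on task."""
        return self.oob_error if self.task == "classification" else self.oob_mse


@dataclass
class FittedForest:
    """Handle bundling the sklearn model with OOB diagnostics.

    ``oob_predictions`` holds the aggregated OOB prediction per training
    sample (NaN where a sample was in every bootstrap); classification
    predictions are reported on the original label scale.
    """

    model: object
    spec: ForestSpec
    performance: ModelPerformance
    importance: ImportanceVector
    classes_: Optional[np.ndarray] = None
    oob_predictions: Optional[np.ndarray] = None


def _as_matrix(X) -> np.ndarray:
    X = X.to_numpy(dtype=float) if hasattr(X, "to_numpy") else np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X.reshape(-1, 1)
    return np.ascontiguousarray(X)


def fit_forest(X, y, spec: ForestSpec, compute_importance: bool = True) -> FittedForest:
    """Fit a forest and compute OOB performance and permutation importance.

    Parameters
    ----------
    X : array-like or DataFrame, shape (n, p)
    y : array-like; continuous (regression) or two-level (classification)
    spec : ForestSpec
    compute_importance : skip the importance pass when only OOB
        performance is needed (e.g. hyperparameter tuning, RFE error
        trajectory tail).
    """
    Xm = _as_matrix(X)
    n, p = Xm.shape
    if p < 1:
        raise ConfigurationError("need at least one feature")
    spec = spec.resolve(p)
    y = np.asarray(y)

    if spec.task == "classification":
        classes, y_enc = np.unique(y, return_inverse=True)
        if classes.size < 2:
            raise DegenerateOutcomeError("classification outcome has a single level")
        counts = np.bincount(y_enc)
        if counts.min() < 2:
            raise DegenerateOutcomeError("need at least 2 samples per class")
        model = RandomForestClassifier(
            n_estimators=spec.n_trees,
            max_features=spec.mtry,
            min_samples_leaf=spec.min_node_size,
            bootstrap=True,
            n_jobs=1,
            random_state=spec.seed,
        )
        model.fit(Xm, y_enc)
        y_num = y_enc.astype(np.int64)
    else:
        y_num = np.asarray(y, dtype=float)
        classes = None
        model = RandomForestRegressor(
            n_estimators=spec.n_trees,
            max_features=spec.mtry,
            min_samples_leaf=spec.min_node_size,
            bootstrap=True,
            n_jobs=1,
            random_state=spec.seed,
        )
        model.fit(Xm, y_num)

    perf, imp_scores, oob_pred = _oob_pass(model, Xm, y_num, spec, compute_importance)
    if spec.task == "classification":
        decoded = np.full(n, np.nan)
        ok = ~np.isnan(oob_pred)
        decoded[ok] = classes[oob_pred[ok].astype(int)]
        oob_pred = decoded
    iv = ImportanceVector.from_scores(
        imp_scores if imp_scores is not None else np.zeros(p),
        names=list(X.columns) if hasattr(X, "columns") else None,
    )
    return FittedForest(model=model, spec=spec, performance=perf,
                        importance=iv, classes_=classes, oob_predictions=oob_pred)


def _oob_pass(model, Xm, y_num, spec, compute_importance):
    """Single pass over the trees: OOB aggregate predictions + importance."""
    n, p = Xm.shape
    is_clf = spec.task == "classification"
    rng = np.random.default_rng(np.uint32(spec.seed) ^ np.uint32(0x5F0F00D))

    imp_sum = np.zeros(p) if compute_importance else None
    if is_clf:
        n_classes = len(model.classes_)
        votes = np.zeros((n, n_classes))
    else:
        pred_sum = np.zeros(n)
        pred_cnt = np.zeros(n, dtype=np.int64)

    for tree, sampled in zip(model.estimators_, model.estimators_samples_):
        in_bag = np.bincount(sampled, minlength=n)
        oob_idx = np.flatnonzero(in_bag == 0)
        if oob_idx.size == 0:
            continue
        t = tree.tree_
        feat = t.feature
        if is_clf:
            leaf_val = np.argmax(t.value[:, 0, :], axis=1).astype(np.int64)
        else:
            leaf_val = t.value[:, 0, 0].astype(np.float64)

        Xo = np.ascontiguousarray(Xm[oob_idx])
        yo = y_num[oob_idx]
        used = np.unique(feat[feat >= 0]).astype(np.int64)
        if compute_importance and used.size:
            m = oob_idx.size
            perms = np.argsort(rng.random((used.size, m)), axis=1).astype(np.int64)
        else:
            used = np.empty(0, dtype=np.int64)
            perms = np.empty((0, oob_idx.size), dtype=np.int64)

        if is_clf:
            _, inc = tree_perm_increase_clf(
                t.children_left, t.children_right, feat, t.threshold,
                leaf_val, Xo, yo.astype(np.int64), used, perms)
            # aggregate votes from the tree's own leaf classes
            leaves = tree.tree_.apply(Xo.astype(np.float32))
            votes[oob_idx, leaf_val[leaves]] += 1.0
        else:
            _, inc = tree_perm_increase_reg(
                t.children_left, t.children_right, feat, t.threshold,
                leaf_val, Xo, yo.astype(np.float64), used, perms)
            leaves = tree.tree_.apply(Xo.astype(np.float32))
            pred_sum[oob_idx] += leaf_val[leaves]
            pred_cnt[oob_idx] += 1
        if compute_importance and used.size:
            imp_sum[used] += inc

    n_trees = len(model.estimators_)
    imp = imp_sum / n_trees if compute_importance else None

    oob_pred = np.full(n, np.nan)
    if is_clf:
        covered = votes.sum(axis=1) > 0
        if not covered.any():
            raise ConfigurationError("no OOB samples; increase n_trees")
        pred = np.argmax(votes[covered], axis=1)
        err = float(np.mean(pred != y_num[covered]))
        perf = ModelPerformance(task="classification", oob_error=err)
        oob_pred[covered] = pred
    else:
        covered = pred_cnt > 0
        if not covered.any():
            raise ConfigurationError("no OOB samples; increase n_trees")
        pred = pred_sum[covered] / pred_cnt[covered]
        mse = float(np.mean((pred - y_num[covered]) ** 2))
        var_y = float(np.var(y_num, ddof=1))
        pct = 100.0 * (1.0 - mse / var_y) if var_y > 0 else float("nan")
        perf = ModelPerformance(task="regression", oob_mse=mse, pct_var_explained=pct)
        oob_pred[covered] = pred
    return perf, imp, oob_pred


def default_tuning_grid(p: int, task: str, n_trees: int = 500, seed: int = 0) -> list[ForestSpec]:
    """mtry grid around the task default: {√p/2, √p, 2√p} for
    classification, {p/10, p/3, p/2} for regression."""
    if task == "classification":
        base = max(int(np.sqrt(p)), 1)
        mtries = sorted({max(base // 2, 1), base, min(2 * base, p)})
    else:
        mtries = sorted({max(p // 10, 1), max(p // 3, 1), max(p // 2, 1)})
    return [ForestSpec(task=task, n_trees=n_trees, mtry=m, seed=seed) for m in mtries]


def tune_hyperparameters(X, y, grid: Iterable[ForestSpec]) -> ForestSpec:
    """Pick the grid member with the smallest OOB loss on (X, y).

    Ties are broken by smaller mtry, then smaller n_trees, so the result
    is deterministic for a deterministic grid.
    """
    grid = list(grid)
    if not grid:
        raise ConfigurationError("empty hyperparameter grid")
    p = _as_matrix(X).shape[1]
    results = []
    for i, spec in enumerate(grid):
        rspec = spec.resolve(p)
        fitted = fit_forest(X, y, rspec, compute_importance=False)
        results.append((fitted.performance.loss, rspec.mtry, rspec.n_trees, i, spec))
    results.sort(key=lambda r: r[:4])
    return results[0][4]
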