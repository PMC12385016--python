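"""Dimensionality reduction and tree-ensemble classification.

Reduction is either a supervised ANOVA-F filter (keep the k features with
the largest between/within-class variance ratio; default k=100) or PCA at
a 95% explained-variance target, always fit on training data only.
Classifiers are a random forest or gradient-boosted trees (XGBoost), with
hyperparameters chosen by grid search under stratified k-fold
cross-validation; ties in mean accuracy are broken toward the simpler
model (fewer trees, then shallower), then by grid order.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from xgboost import XGBClassifier

from .errors import ConfigurationError, DataError, NotFittedError
from .stats import MetricSet, metrics

__all__ = [
    "F_SENTINEL",
    "anova_f_scores",
    "ReductionSpec",
    "ReductionModel",
    "fit_reduction",
    "apply_reduction",
    "ClassifierSpec",
    "FusionPipeline",
    "CvResult",
    "grid_search_cv",
]

#: finite stand-in for an infinite F statistic (zero within-class variance)
F_SENTINEL = 1e12


def anova_f_scores(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """One-way ANOVA F statistic per feature (MSB/MSW, df k-1 and n-k).

    Constant features get F=0; features with zero within-class variance
    but non-zero between-class variance get the finite sentinel.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) < 2:
        raise DataError("ANOVA F requires at least two classes")
    n = len(y)
    grand = X.mean(axis=0)
    ssb = np.zeros(X.shape[1])
    ssw = np.zeros(X.shape[1])
    for c in classes:
        xc = X[y == c]
        mc = xc.mean(axis=0)
        ssb += len(xc) * (mc - grand) ** 2
        ssw += ((xc - mc) ** 2).sum(axis=0)
    msb = ssb / (len(classes) - 1)
    msw = ssw / (n - len(classes))
    constant = np.all(X == X[0], axis=0)  # exactly constant features
    with np.errstate(divide="ignore", invalid="ignore"):
        f = msb / msw
    f = np.where(msw <= 0, np.where(msb > 0, F_SENTINEL, 0.0), f)
    f = np.where(constant, 0.0, f)
    return np.minimum(f, F_SENTINEL)


@dataclass(frozen=True)
class ReductionSpec:
    kind: str = "select_k_best"  # none | select_k_best | pca
    k: int = 100
    variance: float = 0.95

    def __post_init__(self) -> None:
        if self.kind not in ("none", "select_k_best", "pca"):
            raise ConfigurationError(f"unknown reduction kind {self.kind!r}")
        if self.k < 1 or not 0 < self.variance <= 1:
            raise ConfigurationError("k must be >= 1 and variance in (0, 1]")


@dataclass
class ReductionModel:
    spec: ReductionSpec
    selected_indices: np.ndarray | None = None
    f_scores: np.ndarray | None = None
    pca: PCA | None = None
    signs: np.ndarray | None = None
    input_names: tuple[str, ...] | None = None

    @property
    def output_names(self) -> tuple[str, ...]:
        if self.spec.kind == "none":
            return self.input_names or ()
        if self.spec.kind == "select_k_best":
            if self.input_names is None:
                return tuple(f"f_{i}" for i in self.selected_indices)
            return tuple(self.input_names[i] for i in self.selected_indices)
        return tuple(f"pc_{k + 1}" for k in range(self.pca.n_components_))


def fit_reduction(
    X: np.ndarray,
    y: np.ndarray,
    spec: ReductionSpec,
    feature_names: tuple[str, ...] | None = None,
) -> ReductionModel:
    """Fit the reduction on training data only; deterministic."""
    X = np.asarray(X, dtype=float)
    if spec.kind == "none":
        return ReductionModel(spec=spec, input_names=feature_names)
    if spec.kind == "select_k_best":
        f = anova_f_scores(X, y)
        k = spec.k
        if k > X.shape[1]:
            warnings.warn(
                f"k={k} exceeds {X.shape[1]} features; clamping", stacklevel=2
            )
            k = X.shape[1]
        # descending F, ties broken toward the lower index (stable sort)
        order = np.argsort(-f, kind="stable")[:k]
        return ReductionModel(
            spec=spec, selected_indices=order, f_scores=f, input_names=feature_names
        )
    pca = PCA(n_components=spec.variance, svd_solver="full")
    pca.fit(X)
    # sign convention: largest-magnitude loading of each component positive
    signs = np.array(
        [np.sign(c[np.argmax(np.abs(c))]) or 1.0 for c in pca.components_]
    )
    return ReductionModel(spec=spec, pca=pca, signs=signs, input_names=feature_names)


def apply_reduction(model: ReductionModel, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if model.spec.kind == "none":
        return X
    if model.spec.kind == "select_k_best":
        return X[:, model.selected_indices]
    return model.pca.transform(X) * model.signs


# ---------------------------------------------------------------------------
# classifiers
# ---------------------------------------------------------------------------

DEFAULT_FOREST_GRID = {"n_estimators": [100, 300, 500], "max_depth": [None, 10, 20]}
DEFAULT_BOOSTED_GRID = {
    "learning_rate": [0.05, 0.1, 0.3],
    "max_depth": [3, 6],
    "min_child_weight": [1, 5],
}


@dataclass(frozen=True)
class ClassifierSpec:
    kind: str = "random_forest"  # random_forest | gradient_boosted_trees
    grid: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("random_forest", "gradient_boosted_trees"):
            raise ConfigurationError(f"unknown classifier kind {self.kind!r}")
        if self.grid == {}:
            default = (
                DEFAULT_FOREST_GRID if self.kind == "random_forest" else DEFAULT_BOOSTED_GRID
            )
            object.__setattr__(self, "grid", {k: list(v) for k, v in default.items()})
        if any(len(v) == 0 for v in self.grid.values()):
            raise ConfigurationError("hyperparameter grid axes must be non-empty")

    def build(self, params: dict):
        if self.kind == "random_forest":
            return RandomForestClassifier(random_state=self.seed, n_jobs=1, **params)
        return XGBClassifier(
            n_estimators=100,
            base_score=0.5,
            eval_metric="logloss",
            random_state=self.seed,
            n_jobs=1,
            tree_method="hist",
            **params,
        )

    def grid_candidates(self) -> list[dict]:
        """All grid points ordered by model complexity, then grid order."""
        keys = list(self.grid)
        cands = [dict(zip(keys, vals)) for vals in itertools.product(*(self.grid[k] for k in keys))]

        def complexity(c: dict) -> tuple:
            trees = c.get("n_estimators", 0)
            depth = c.get("max_depth", None)
            depth = np.inf if depth is None else depth
            return (trees, depth)

        order = sorted(range(len(cands)), key=lambda i: (complexity(cands[i]), i))
        return [cands[i] for i in order]


class FusionPipeline:
    """Reduction + tree-ensemble classifier, fit as one unit."""

    def __init__(
        self,
        reduction_spec: ReductionSpec = ReductionSpec(),
        classifier_spec: ClassifierSpec = ClassifierSpec(),
        params: dict | None = None,
        feature_names: tuple[str, ...] | None = None,
    ):
        self.reduction_spec = reduction_spec
        self.classifier_spec = classifier_spec
        self.params = params if params is not None else classifier_spec.grid_candidates()[0]
        self.feature_names = feature_names
        self.reduction: ReductionModel | None = None
        self.model = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "FusionPipeline":
        self.reduction = fit_reduction(X, y, self.reduction_spec, self.feature_names)
        Xr = apply_reduction(self.reduction, X)
        self.model = self.classifier_spec.build(self.params)
        self.model.fit(Xr, np.asarray(y, dtype=int))
        return self

    def _check_fitted(self) -> None:
        if self.model is None:
            raise NotFittedError("pipeline is not fitted")

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Probability of the lesion class, one value in [0, 1] per sample."""
        self._check_fitted()
        Xr = apply_reduction(self.reduction, X)
        return self.model.predict_proba(Xr)[:, 1]

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_proba(X) >= 0.5).astype(int)

    @property
    def reduced_feature_names(self) -> tuple[str, ...]:
        self._check_fitted()
        names = self.reduction.output_names
        if names:
            return names
        n = getattr(self.model, "n_features_in_", 0)
        return tuple(f"f_{i}" for i in range(n))


@dataclass
class CvResult:
    """Per-fold metrics and the grid-search choice."""

    fold_metrics: list[MetricSet]
    best_params: dict
    fold_assignment: np.ndarray
    seed: int

    def fold_scores(self, metric: str = "accuracy") -> np.ndarray:
        return np.array([getattr(m, metric) for m in self.fold_metrics])

    def mean(self, metric: str = "accuracy") -> float:
        return float(self.fold_scores(metric).mean())

    def sd(self, metric: str = "accuracy") -> float:
        return float(self.fold_scores(metric).std(ddof=1))

    def to_dict(self) -> dict:
        return {
            "best_params": self.best_params,
            "seed": self.seed,
            "folds": [m.to_dict() for m in self.fold_metrics],
            "mean_accuracy": self.mean("accuracy"),
            "sd_accuracy": self.sd("accuracy"),
            "mean_auc": self.mean("auc"),
        }


def _fold_ids(y: np.ndarray, folds: int, seed: int) -> np.ndarray:
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    assignment = np.empty(len(y), dtype=int)
    for k, (_, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        assignment[test_idx] = k
    return assignment


def grid_search_cv(
    X: np.ndarray,
    y: np.ndarray,
    classifier_spec: ClassifierSpec = ClassifierSpec(),
    reduction_spec: ReductionSpec = ReductionSpec(),
    folds: int = 5,
    seed: int = 0,
    X_eval: np.ndarray | None = None,
    feature_names: tuple[str, ...] | None = None,
    selection_metric: str = "accuracy",
) -> tuple[CvResult, FusionPipeline]:
    """Grid search with stratified k-fold CV; reduction fit inside each fold.

    ``X_eval`` optionally supplies a second feature matrix (same rows) used
    only for held-out-fold evaluation — this is how feature-level TTA is
    applied at inference time without touching the training folds.

    Returns the per-fold metrics for the winning hyperparameters and the
    final pipeline refit on all provided data.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    X_eval = X if X_eval is None else np.asarray(X_eval, dtype=float)
    if X_eval.shape != X.shape:
        raise DataError("X_eval must have the same shape as X")
    counts = np.bincount(y)
    if (counts[counts > 0] < folds).any():
        raise DataError(f"each class needs >= {folds} samples for {folds}-fold CV")
    fold_ids = _fold_ids(y, folds, seed)

    candidates = classifier_spec.grid_candidates()
    best_score, best_params, best_metrics = -np.inf, None, None
    for params in candidates:
        fold_metrics = []
        for k in range(folds):
            tr, te = fold_ids != k, fold_ids == k
            pipe = FusionPipeline(reduction_spec, classifier_spec, params, feature_names)
            pipe.fit(X[tr], y[tr])
            prob = pipe.predict_proba(X_eval[te])
            fold_metrics.append(metrics(y[te], (prob >= 0.5).astype(int), prob))
        score = float(np.mean([getattr(m, selection_metric) for m in fold_metrics]))
        if score > best_score:
            best_score, best_params, best_metrics = score, params, fold_metrics

    result = CvResult(
        fold_metrics=best_metrics, best_params=best_params, fold_assignment=fold_ids, seed=seed
    )
    final = FusionPipeline(reduction_spec, classifier_spec, best_params, feature_names)
    final.fit(X, y)
    return result, final
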