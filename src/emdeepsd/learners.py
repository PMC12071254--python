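"""Per-subsequence base learners and stacked meta-features.

Each decomposition subsequence matrix (samples x 256) is modelled
independently by five algorithm families — L1-penalised logistic
regression (LASSO), elastic-net logistic regression, random forest,
gradient-boosted trees (XGBoost) and a multilayer perceptron — with
hyperparameters selected by 10-fold stratified cross-validated AUC. The
class-1 probabilities of the fitted models are the meta-features that
feed the downstream meta-network: during training they are *out-of-fold*
predictions (each sample scored by models that never saw its fold), at
prediction time they come from the full-data refits. An SSA stack (3
subsequences x 5 algorithms) yields 15 meta-feature columns; an EMD
stack yields 10.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold, cross_val_predict
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from xgboost import XGBClassifier

ALGORITHMS = (
    "lasso_logistic",
    "elastic_net_logistic",
    "random_forest",
    "gradient_boosted_trees",
    "multilayer_perceptron",
)

#: default hyperparameter search grids (keys are sklearn param names on the
#: estimator step of the pipeline)
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "lasso_logistic": {"model__C": list(np.logspace(-3, 2, 20))},
    "elastic_net_logistic": {
        "model__C": list(np.logspace(-3, 2, 20)),
        "model__l1_ratio": [0.1, 0.3, 0.5, 0.7, 0.9],
    },
    "random_forest": {
        "model__n_estimators": [500],
        "model__max_features": [8, 16, 32],
    },
    "gradient_boosted_trees": {
        "model__max_depth": [2, 3],
        "model__n_estimators": [200],
        "model__learning_rate": [0.1],
    },
    "multilayer_perceptron": {"model__hidden_layer_sizes": [(16,), (32,)]},
}

#: reduced grids for desk-scale runs (single point or pair per algorithm)
FAST_GRIDS: dict[str, dict[str, list]] = {
    "lasso_logistic": {"model__C": [0.01, 0.1, 1.0, 10.0]},
    "elastic_net_logistic": {
        "model__C": [0.01, 0.1, 1.0],
        "model__l1_ratio": [0.5],
    },
    "random_forest": {
        "model__n_estimators": [100],
        "model__max_features": [16],
    },
    "gradient_boosted_trees": {
        "model__max_depth": [2],
        "model__n_estimators": [100],
        "model__learning_rate": [0.1],
    },
    "multilayer_perceptron": {"model__hidden_layer_sizes": [(16,)]},
}


@dataclass
class LearnerSpec:
    """One base-learner family with its hyperparameter search grid."""

    algorithm: str
    hyperparameter_grid: Mapping[str, list] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(
                f"unknown algorithm {self.algorithm!r}; expected one of {ALGORITHMS}"
            )
        if not self.hyperparameter_grid:
            self.hyperparameter_grid = DEFAULT_GRIDS[self.algorithm]


def default_specs(seed: int = 0, fast: bool = False) -> list[LearnerSpec]:
    grids = FAST_GRIDS if fast else DEFAULT_GRIDS
    return [LearnerSpec(alg, grids[alg], seed=seed) for alg in ALGORITHMS]


def _make_estimator(spec: LearnerSpec):
    seed = spec.seed
    if spec.algorithm == "lasso_logistic":
        model = LogisticRegression(
            l1_ratio=1.0, solver="liblinear", max_iter=2000, random_state=seed
        )
        steps = [("scale", StandardScaler()), ("model", model)]
    elif spec.algorithm == "elastic_net_logistic":
        model = LogisticRegression(
            solver="saga",
            l1_ratio=0.5,
            max_iter=2000,
            tol=1e-3,
            random_state=seed,
        )
        steps = [("scale", StandardScaler()), ("model", model)]
    elif spec.algorithm == "random_forest":
        model = RandomForestClassifier(random_state=seed, n_jobs=1)
        steps = [("model", model)]
    elif spec.algorithm == "gradient_boosted_trees":
        model = XGBClassifier(
            tree_method="hist",
            n_jobs=1,
            random_state=seed,
            eval_metric="logloss",
            verbosity=0,
        )
        steps = [("model", model)]
    elif spec.algorithm == "multilayer_perceptron":
        # lbfgs converges reliably on the small cohorts this tool targets
        model = MLPClassifier(
            solver="lbfgs",
            max_iter=500,
            random_state=seed,
        )
        steps = [("scale", StandardScaler()), ("model", model)]
    else:  # pragma: no cover - guarded by LearnerSpec
        raise ValueError(spec.algorithm)
    return Pipeline(steps)


def _check_y(y: np.ndarray, folds: int) -> np.ndarray:
    y = np.asarray(y, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("both classes must be present in y")
    minority = counts.min()
    if folds > minority:
        raise ValueError(
            f"{folds}-fold CV impossible with minority class of {minority} "
            f"samples; use at most {minority} folds"
        )
    return y


def tune_and_fit(X_sub: np.ndarray, y: np.ndarray, spec: LearnerSpec,
                 folds: int = 10) -> GridSearchCV:
    """Select hyperparameters by stratified k-fold CV AUC and refit on all data."""
    y = _check_y(y, folds)
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=spec.seed)
    search = GridSearchCV(
        _make_estimator(spec),
        param_grid=dict(spec.hyperparameter_grid),
        scoring="roc_auc",
        cv=cv,
        refit=True,
        n_jobs=1,
    )
    search.fit(np.asarray(X_sub, dtype=float), y)
    return search


@dataclass
class MetaFeatureMatrix:
    """Samples x base-learner class-1 probabilities."""

    sample_ids: list[str]
    columns: list[str]  # "<subsequence>:<algorithm>", subsequence-major
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.columns)):
            raise ValueError("meta-feature shape mismatch")
        if ((self.values < 0) | (self.values > 1)).any():
            raise ValueError("meta-features must be probabilities in [0, 1]")


@dataclass
class FittedStack:
    """All tuned base learners for one decomposition variant."""

    subsequence_names: list[str]
    columns: list[str]
    models: dict[str, object]  # column name -> fitted estimator
    folds: int
    seed: int


def build_meta_features_train(
    subsequences: Mapping[str, np.ndarray],
    y: np.ndarray,
    sample_ids: Sequence[str],
    specs: Sequence[LearnerSpec] | None = None,
    folds: int = 10,
    seed: int = 0,
    fast: bool = False,
) -> tuple[MetaFeatureMatrix, FittedStack]:
    """Tune, fit and emit out-of-fold training meta-features.

    For every (subsequence, algorithm) pair the grid is searched by
    k-fold CV, the winning configuration is refit on all samples (kept in
    the returned stack for prediction), and the training meta-feature
    column is the out-of-fold probability from ``cross_val_predict`` with
    that configuration over the same seeded folds.
    """
    if specs is None:
        specs = default_specs(seed=seed, fast=fast)
    y = _check_y(y, folds)
    n = y.size
    names = list(subsequences)
    for name, mat in subsequences.items():
        if np.asarray(mat).shape[0] != n:
            raise ValueError(
                f"subsequence {name!r} has {np.asarray(mat).shape[0]} rows; "
                f"labels have {n} (sample order must match)"
            )
    if len(sample_ids) != n:
        raise ValueError("sample_ids length must match labels")
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    columns: list[str] = []
    models: dict[str, object] = {}
    cols: list[np.ndarray] = []
    for name in names:
        X_sub = np.asarray(subsequences[name], dtype=float)
        for spec in specs:
            search = tune_and_fit(X_sub, y, spec, folds=folds)
            best = clone(search.best_estimator_)
            oof = cross_val_predict(
                best, X_sub, y, cv=cv, method="predict_proba", n_jobs=1
            )[:, 1]
            col = f"{name}:{spec.algorithm}"
            columns.append(col)
            models[col] = search.best_estimator_
            cols.append(oof)
    meta = MetaFeatureMatrix(
        sample_ids=list(sample_ids), columns=columns,
        values=np.column_stack(cols),
    )
    stack = FittedStack(
        subsequence_names=names, columns=columns, models=models,
        folds=folds, seed=seed,
    )
    return meta, stack


def predict_meta(
    stack: FittedStack,
    subsequences: Mapping[str, np.ndarray],
    sample_ids: Sequence[str],
) -> MetaFeatureMatrix:
    """Meta-features for new samples from the full-data refits."""
    missing = [n for n in stack.subsequence_names if n not in subsequences]
    if missing:
        raise ValueError(f"missing subsequence matrices: {missing}")
    cols = []
    for col in stack.columns:
        name, _, _alg = col.partition(":")
        X_sub = np.asarray(subsequences[name], dtype=float)
        cols.append(stack.models[col].predict_proba(X_sub)[:, 1])
    return MetaFeatureMatrix(
        sample_ids=list(sample_ids), columns=list(stack.columns),
        values=np.column_stack(cols),
    )
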