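"""Grid-searched machine-learning regressors over panel dosage matrices.

Four model families — SVR, random forest, kernel ridge, gradient boosting —
are tuned by exhaustive grid search scored with the mean Pearson
correlation under repeated 5-fold cross-validation inside the training set,
then refit on the full training data.  The tuning criterion matches the
accuracy metric used to evaluate genomic predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.kernel_ridge import KernelRidge
from sklearn.model_selection import GridSearchCV, RepeatedKFold
from sklearn.svm import SVR
from xgboost import XGBRegressor

MODELS = ("SVR", "RF", "KRR", "XGB")

# Package defaults; every entry overridable through MlSpec.grid.
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "SVR": {"C": [0.1, 1.0, 10.0], "gamma": ["scale", 0.01]},
    "RF": {"n_estimators": [200, 500], "max_features": ["sqrt", 0.3]},
    "KRR": {"alpha": [0.1, 1.0, 10.0], "gamma": [1e-4, 1e-3]},
    "XGB": {
        "max_depth": [3, 6],
        "learning_rate": [0.05, 0.1],
        "n_estimators": [200, 500],
    },
}


@dataclass
class MlSpec:
    model: str
    grid: dict[str, list] | None = None
    inner_cv_folds: int = 5
    inner_cv_repeats: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r} (choose from {MODELS})")
        if self.grid is None:
            self.grid = {k: list(v) for k, v in DEFAULT_GRIDS[self.model].items()}
        if not self.grid or any(len(v) == 0 for v in self.grid.values()):
            raise ValueError("grid must be non-empty")
        if self.inner_cv_folds < 2:
            raise ValueError("inner_cv_folds must be >= 2")


@dataclass
class FittedMl:
    spec: MlSpec
    estimator: object
    best_params: dict
    best_score: float
    n_features: int
    history: object = field(repr=False, default=None)


def _pearson_score(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    if np.std(y_pred) == 0 or np.std(y_true) == 0:
        return 0.0
    return float(stats.pearsonr(y_true, y_pred)[0])


def _make_estimator(spec: MlSpec):
    if spec.model == "SVR":
        return SVR(kernel="rbf")
    if spec.model == "RF":
        return RandomForestRegressor(random_state=spec.seed, n_jobs=1)
    if spec.model == "KRR":
        return KernelRidge(kernel="rbf")
    return XGBRegressor(
        random_state=spec.seed,
        n_jobs=1,
        tree_method="hist",
        verbosity=0,
        objective="reg:squarederror",
    )


def tune_and_fit(X_train: np.ndarray, y_train: np.ndarray, spec: MlSpec) -> FittedMl:
    """Exhaustive grid search with repeated inner CV, then refit on all data.

    Deterministic for a fixed ``spec.seed`` (inner folds and every
    stochastic estimator are seeded from it).
    """
    X = np.asarray(X_train, dtype=float)
    y = np.asarray(y_train, dtype=float)
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("missing values in training data")
    if np.std(y) == 0:
        raise ValueError("constant y_train: correlation criterion undefined")
    cv = RepeatedKFold(
        n_splits=spec.inner_cv_folds,
        n_repeats=spec.inner_cv_repeats,
        random_state=spec.seed,
    )
    search = GridSearchCV(
        _make_estimator(spec),
        spec.grid,
        scoring=lambda est, Xv, yv: _pearson_score(yv, est.predict(Xv)),
        cv=cv,
        n_jobs=1,
        refit=True,
    )
    search.fit(X, y)
    return FittedMl(
        spec=spec,
        estimator=search.best_estimator_,
        best_params=dict(search.best_params_),
        best_score=float(search.best_score_),
        n_features=X.shape[1],
        history=search.cv_results_,
    )


def predict(fitted: FittedMl, X_test: np.ndarray) -> np.ndarray:
    X = np.asarray(X_test, dtype=float)
    if X.shape[1] != fitted.n_features:
        raise ValueError(
            f"feature count {X.shape[1]} does not match training ({fitted.n_features})"
        )
    out = np.asarray(fitted.estimator.predict(X), dtype=float)
    if not np.isfinite(out).all():
        raise ValueError("non-finite predictions")
    return out
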