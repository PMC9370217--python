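"""Non-linear baseline regressors on a fixed descriptor subset.

Five standard machine-learning regressors (k-NN, random forest, support
vector, multilayer perceptron, gradient boosting) are tuned by grid
search under a shared 5-fold cross-validation and refit on the full
training set — the comparison partner for the linear model built on the
same descriptors. Distance- and gradient-based methods (k-NN, SVM, MLP)
are wrapped in a standardization pipeline.

The default grids are deliberately small and user-overridable: the
contract is the comparison protocol (shared folds, CV-R^2 selection,
external R^2_Pred), not any particular grid.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.neighbors import KNeighborsRegressor
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

METHODS = ("kNN", "RF", "SVM", "MLP", "GB")

DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "kNN": {"est__n_neighbors": [3, 5, 7, 9], "est__weights": ["uniform", "distance"]},
    "RF": {"est__n_estimators": [100, 300], "est__max_depth": [None, 5, 10]},
    "SVM": {
        "est__kernel": ["rbf", "linear"],
        "est__C": [1.0, 10.0, 100.0],
        "est__epsilon": [0.01, 0.1],
    },
    "MLP": {
        "est__hidden_layer_sizes": [(50,), (100,)],
        "est__alpha": [1e-4, 1e-2],
    },
    "GB": {"est__n_estimators": [100, 300], "est__learning_rate": [0.05, 0.1]},
}

_SCALED = {"kNN", "SVM", "MLP"}


def _estimator(method: str, rng_seed: int):
    if method == "kNN":
        return KNeighborsRegressor()
    if method == "RF":
        return RandomForestRegressor(random_state=rng_seed)
    if method == "SVM":
        return SVR()
    if method == "MLP":
        return MLPRegressor(random_state=rng_seed, max_iter=3000)
    if method == "GB":
        return GradientBoostingRegressor(random_state=rng_seed)
    raise ValueError(f"unknown method '{method}' (choose from {METHODS})")


def tune_and_fit(
    features: pd.DataFrame,
    y: Sequence[float],
    method: str,
    grid: dict[str, list] | None = None,
    cv_folds: int = 5,
    rng_seed: int = 0,
):
    """Grid search scored by mean ``cv_folds``-fold CV R^2, refit on all rows.

    The fold assignment is derived from ``rng_seed`` alone, so every
    method tuned with the same seed sees the same folds. Returns
    ``(fitted_pipeline, q2_cv)`` where ``q2_cv`` is the best mean CV R^2.
    """
    steps = []
    if method in _SCALED:
        steps.append(("scale", StandardScaler()))
    steps.append(("est", _estimator(method, rng_seed)))
    pipe = Pipeline(steps)
    folds = KFold(n_splits=cv_folds, shuffle=True, random_state=rng_seed)
    search = GridSearchCV(
        pipe,
        grid if grid is not None else DEFAULT_GRIDS[method],
        scoring="r2",
        cv=folds,
        refit=True,
    )
    search.fit(features.to_numpy(dtype=float), np.asarray(y, dtype=float))
    return search.best_estimator_, float(search.best_score_)


def baseline_table(
    train_features: pd.DataFrame,
    train_y: Sequence[float],
    eval_sets: dict[str, tuple[pd.DataFrame, Sequence[float]]],
    methods: Sequence[str] = METHODS,
    grids: dict[str, dict] | None = None,
    cv_folds: int = 5,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Tune every method and tabulate CV and external performance."""
    from .validation import r2_pred

    train_mean = float(np.mean(np.asarray(train_y, dtype=float)))
    rows = []
    for method in methods:
        grid = (grids or {}).get(method)
        est, q2cv = tune_and_fit(train_features, train_y, method, grid, cv_folds, rng_seed)
        row = {"method": method, "q2_cv": q2cv}
        for label, (X, yv) in eval_sets.items():
            pred = est.predict(X.to_numpy(dtype=float))
            row[f"r2_pred_{label}"] = r2_pred(yv, pred, train_mean)
        rows.append(row)
    return pd.DataFrame(rows)
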