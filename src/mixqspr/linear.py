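"""Ordinary least squares and sequential forward selection (SFS-MLR).

The model-building engine: an OLS fit with per-coefficient standard
errors, and a greedy forward selection over candidate WM descriptors.
At each step the candidate maximizing the chosen scoring criterion is
provisionally added; the addition is kept only if it reduces the
leave-one-out mean absolute error (MAE_LOO) of the incumbent model by at
least ``mae_reduction`` (default 5%). Selection stops at the first
rejected addition, which keeps the descriptor count minimal and makes
models built under different scorings comparable.

MAE_LOO inside the policy uses the exact OLS hat-matrix identity
``e_loo_i = e_i / (1 - h_i)`` — identical to literally refitting N times,
at a fraction of the cost.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.model_selection import KFold
from sklearn.utils.validation import check_is_fitted

from .errors import MissingFeatureError, SingularityError

SCORINGS = ("R2", "NMAE", "NMPD", "R2_cv5", "R2_cv10")

_POISSON_CLIP = 1e-6


@dataclass
class LinearModel:
    """A fitted MLR model: selected features, coefficients, fit statistics.

    ``rho`` is the ratio of training points to adjustable variables
    (features, excluding the intercept) — a crude overfitting guard.
    """

    feature_names: tuple[str, ...]
    coef: np.ndarray
    intercept: float
    coef_se: np.ndarray
    intercept_se: float
    r2: float
    r2_adj: float
    f_stat: float
    n_train: int
    rho: float
    residual_sd: float
    warning: str | None = None
    trace: list[dict] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        """Row-wise ``intercept + sum(coef * feature)``."""
        for name in self.feature_names:
            if name not in features.columns:
                raise MissingFeatureError(name)
        if not self.feature_names:
            return np.full(len(features), self.intercept)
        X = features[list(self.feature_names)].to_numpy(dtype=float)
        return self.intercept + X @ self.coef

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "format": "mixqspr-linear-model",
            "version": 1,
            "feature_names": list(self.feature_names),
            "coef": [float(c) for c in self.coef],
            "intercept": float(self.intercept),
            "coef_se": [float(s) for s in self.coef_se],
            "intercept_se": float(self.intercept_se),
            "stats": {
                "r2": self.r2,
                "r2_adj": self.r2_adj,
                "f_stat": self.f_stat,
                "n_train": self.n_train,
                "rho": self.rho,
                "residual_sd": self.residual_sd,
            },
            "warning": self.warning,
            "trace": self.trace,
            "metadata": self.metadata,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "LinearModel":
        text = Path(source).read_text() if isinstance(source, Path) or (
            isinstance(source, str) and not source.lstrip().startswith("{")
        ) else str(source)
        payload = json.loads(text)
        stats = {
            k: (math.nan if v is None else v)
            for k, v in payload.get("stats", {}).items()
        }
        return cls(
            feature_names=tuple(payload["feature_names"]),
            coef=np.asarray(payload["coef"], dtype=float),
            intercept=float(payload["intercept"]),
            coef_se=np.asarray(payload.get("coef_se", [math.nan] * len(payload["coef"]))),
            intercept_se=float(payload.get("intercept_se", math.nan)),
            r2=stats.get("r2", math.nan),
            r2_adj=stats.get("r2_adj", math.nan),
            f_stat=stats.get("f_stat", math.nan),
            n_train=int(stats.get("n_train", 0)),
            rho=stats.get("rho", math.nan),
            residual_sd=stats.get("residual_sd", math.nan),
            warning=payload.get("warning"),
            trace=payload.get("trace", []),
            metadata=payload.get("metadata", {}),
        )


def _design(X: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones(X.shape[0]), X])


def _dependent_columns(X: np.ndarray, names: Sequence[str]) -> list[str]:
    """Columns that do not increase the rank when added left to right."""
    bad, cols = [], []
    rank = 1  # the intercept
    current = np.ones((X.shape[0], 1))
    for j, name in enumerate(names):
        trial = np.column_stack([current, X[:, j]])
        r = np.linalg.matrix_rank(trial)
        if r > rank:
            current, rank = trial, r
        else:
            bad.append(name)
    return bad


def fit_ols(features: pd.DataFrame, y: Sequence[float] | pd.Series) -> LinearModel:
    """Least-squares fit with standard errors and summary statistics.

    A constant response yields zero slopes and, by convention, R^2 = 0
    (the total sum of squares is zero; the model explains nothing beyond
    the mean).
    """
    names = tuple(features.columns)
    X = features.to_numpy(dtype=float)
    yv = np.asarray(y, dtype=float)
    n, p = X.shape
    if n < p + 2:
        raise ValueError(f"need at least {p + 2} rows to fit {p} features, got {n}")
    if np.isnan(X).any() or np.isnan(yv).any():
        raise ValueError("missing values in design or response")
    Xd = _design(X)
    if np.linalg.matrix_rank(Xd) < p + 1:
        raise SingularityError(_dependent_columns(X, names))
    XtX_inv = np.linalg.inv(Xd.T @ Xd)
    beta = XtX_inv @ Xd.T @ yv
    fitted = Xd @ beta
    resid = yv - fitted
    sse = float(resid @ resid)
    sst = float(np.sum((yv - yv.mean()) ** 2))
    dof = n - p - 1
    s2 = sse / dof if dof > 0 else math.nan
    se = np.sqrt(np.maximum(s2 * np.diag(XtX_inv), 0.0))
    if sst > 0:
        r2 = 1.0 - sse / sst
        r2_adj = 1.0 - (1.0 - r2) * (n - 1) / dof if dof > 0 else math.nan
        f_stat = (r2 / p) / ((1.0 - r2) / dof) if p > 0 and r2 < 1.0 else math.inf if p > 0 else 0.0
    else:
        r2, r2_adj, f_stat = 0.0, 0.0, 0.0
    return LinearModel(
        feature_names=names,
        coef=beta[1:],
        intercept=float(beta[0]),
        coef_se=se[1:],
        intercept_se=float(se[0]),
        r2=r2,
        r2_adj=r2_adj,
        f_stat=f_stat,
        n_train=n,
        rho=n / p if p > 0 else math.inf,
        residual_sd=math.sqrt(s2) if dof > 0 else math.nan,
    )


def leverages(features: pd.DataFrame) -> np.ndarray:
    """Diagonal of the hat matrix for the intercept-augmented design."""
    Xd = _design(features.to_numpy(dtype=float))
    XtX_inv = np.linalg.inv(Xd.T @ Xd)
    return np.einsum("ij,jk,ik->i", Xd, XtX_inv, Xd)


def loo_residuals(features: pd.DataFrame, y: Sequence[float]) -> np.ndarray:
    """Exact leave-one-out prediction errors ``y_i - yhat_(-i)``.

    Uses ``e_i / (1 - h_i)``; equal to refitting without row i.
    """
    yv = np.asarray(y, dtype=float)
    Xd = _design(features.to_numpy(dtype=float))
    XtX_inv = np.linalg.inv(Xd.T @ Xd)
    beta = XtX_inv @ Xd.T @ yv
    resid = yv - Xd @ beta
    h = np.einsum("ij,jk,ik->i", Xd, XtX_inv, Xd)
    if np.any(h >= 1.0 - 1e-12):
        raise SingularityError(["<leverage 1 row: LOO refit singular>"])
    return resid / (1.0 - h)


def mae_loo(features: pd.DataFrame, y: Sequence[float]) -> float:
    """Leave-one-out cross-validated mean absolute error."""
    return float(np.mean(np.abs(loo_residuals(features, y))))


def _score(features: pd.DataFrame, y: np.ndarray, scoring: str, cv_seed: int) -> float:
    if scoring == "R2":
        return fit_ols(features, y).r2
    if scoring == "NMAE":
        model = fit_ols(features, y)
        return -float(np.mean(np.abs(y - model.predict(features))))
    if scoring == "NMPD":
        model = fit_ols(features, y)
        mu = np.clip(model.predict(features), _POISSON_CLIP, None)
        if np.any(y <= 0):
            raise ValueError("Poisson deviance requires positive responses")
        dev = 2.0 * (y * np.log(y / mu) - (y - mu))
        return -float(np.mean(dev))
    if scoring in ("R2_cv5", "R2_cv10"):
        n_splits = 5 if scoring == "R2_cv5" else 10
        kf = KFold(n_splits=n_splits, shuffle=True, random_state=cv_seed)
        scores = []
        for tr, va in kf.split(features):
            model = fit_ols(features.iloc[tr], y[tr])
            pred = model.predict(features.iloc[va])
            sse = np.sum((y[va] - pred) ** 2)
            sst = np.sum((y[va] - y[va].mean()) ** 2)
            scores.append(1.0 - sse / sst if sst > 0 else 0.0)
        return float(np.mean(scores))
    raise ValueError(f"unknown scoring '{scoring}' (choose from {SCORINGS})")


def sfs_select(
    features: pd.DataFrame,
    y: Sequence[float] | pd.Series,
    scoring: str = "R2",
    mae_reduction: float = 0.05,
    max_features: int | None = None,
    cv_seed: int = 0,
) -> LinearModel:
    """Greedy forward selection gated by the %MAE_LOO reduction policy.

    At each step every remaining candidate is scored (model with the
    incumbent features plus that candidate, refit by OLS); the best-scoring
    candidate (ties -> lowest column index) is accepted only if the
    enlarged model's MAE_LOO is at most ``(1 - mae_reduction)`` times the
    incumbent's. The first rejection terminates selection. If no candidate
    survives step 1 the intercept-only model is returned with a warning
    flag. The selection trace is stored on the returned model.
    """
    yv = np.asarray(y, dtype=float)
    columns = list(features.columns)
    selected: list[str] = []
    empty = features[[]]
    incumbent_mae = mae_loo(empty, yv)
    trace: list[dict] = []
    warning = None
    while columns and (max_features is None or len(selected) < max_features):
        best_name, best_score = None, -math.inf
        for name in columns:  # input order; ties keep the earlier column
            try:
                s = _score(features[selected + [name]], yv, scoring, cv_seed)
            except SingularityError:
                continue
            if s > best_score:
                best_name, best_score = name, s
        if best_name is None:
            break
        candidate_mae = mae_loo(features[selected + [best_name]], yv)
        accepted = candidate_mae <= (1.0 - mae_reduction) * incumbent_mae
        trace.append(
            {
                "step": len(trace) + 1,
                "candidate": best_name,
                "score": best_score,
                "mae_loo_before": incumbent_mae,
                "mae_loo_after": candidate_mae,
                "accepted": accepted,
            }
        )
        if not accepted:
            break
        selected.append(best_name)
        columns.remove(best_name)
        incumbent_mae = candidate_mae
    if not selected:
        warning = "no candidate met the MAE_LOO reduction policy; intercept-only model"
    model = fit_ols(features[selected], yv)
    model.trace = trace
    model.warning = warning
    model.metadata = {"scoring": scoring, "mae_reduction": mae_reduction, "cv_seed": cv_seed}
    return model


def predict(model: LinearModel, features: pd.DataFrame) -> np.ndarray:
    """Functional alias for :meth:`LinearModel.predict`."""
    return model.predict(features)


class ForwardSelectionMLR(BaseEstimator, RegressorMixin):
    """scikit-learn estimator wrapping :func:`sfs_select`.

    Parameters
    ----------
    scoring : {"R2", "NMAE", "NMPD", "R2_cv5", "R2_cv10"}
        Criterion used to pick the best candidate at each step.
    mae_reduction : float
        Minimum fractional MAE_LOO reduction an accepted step must achieve.
    max_features : int or None
        Optional hard cap on the number of selected descriptors.
    cv_seed : int
        Fold seed for the cross-validated scorings.
    """

    def __init__(
        self,
        scoring: str = "R2",
        mae_reduction: float = 0.05,
        max_features: int | None = None,
        cv_seed: int = 0,
    ):
        self.scoring = scoring
        self.mae_reduction = mae_reduction
        self.max_features = max_features
        self.cv_seed = cv_seed

    def fit(self, X: pd.DataFrame, y) -> "ForwardSelectionMLR":
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float))
            X.columns = [f"x{j}" for j in range(X.shape[1])]
        self.model_ = sfs_select(
            X,
            y,
            scoring=self.scoring,
            mae_reduction=self.mae_reduction,
            max_features=self.max_features,
            cv_seed=self.cv_seed,
        )
        self.selected_features_ = list(self.model_.feature_names)
        self.coef_ = self.model_.coef
        self.intercept_ = self.model_.intercept
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float))
            X.columns = [f"x{j}" for j in range(X.shape[1])]
        return self.model_.predict(X)
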