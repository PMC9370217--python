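"""Model-validation battery for mixture QSPR models.

Internal predictivity: leave-one-out (LOO) and leave-chemical-out (LCO)
cross-validation. External predictivity: R^2_Pred against the training
mean, mean absolute error, %AARD / per-record %RD, and the scaled rm^2
metric family. Chance correlation: Y-randomization with the cRp^2
parameter. Applicability domain: leverage against the warning value
h* = 3(p+1)/n, visualized as a Williams plot (standardized residual vs
leverage).

LOO statistics use the exact OLS hat-matrix identity and therefore agree
with a literal N-refit loop to machine precision. LCO removes every
record containing a given chemical (in either role), refits the
*coefficients* on the remainder with the feature subset frozen, predicts
the held-out records, and pools all held-out predictions before computing
Q^2_LCO and MAE_LCO.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .data import MixtureDataset
from .linear import LinearModel, fit_ols, leverages, loo_residuals


@dataclass
class ValidationReport:
    """The full metric battery for one (model, split) pair."""

    q2_loo: float = math.nan
    mae_loo: float = math.nan
    q2_lco: float = math.nan
    mae_lco: float = math.nan
    lco_skipped: list[str] = field(default_factory=list)
    external: dict[str, dict[str, float]] = field(default_factory=dict)
    rm2: dict[str, dict[str, float]] = field(default_factory=dict)
    aard_train: float = math.nan

    def to_dict(self) -> dict:
        flat = {
            "q2_loo": self.q2_loo,
            "mae_loo": self.mae_loo,
            "q2_lco": self.q2_lco,
            "mae_lco": self.mae_lco,
            "aard_train": self.aard_train,
            "lco_skipped": list(self.lco_skipped),
        }
        for set_name, metrics in self.external.items():
            for k, v in metrics.items():
                flat[f"{k}_{set_name}"] = v
        for set_name, metrics in self.rm2.items():
            for k, v in metrics.items():
                flat[f"{k}_{set_name}"] = v
        return flat


@dataclass
class RandomizationReport:
    n_runs: int
    model_r: float
    mean_randomized_r2: float
    crp2: float


@dataclass
class ADReport:
    """Leverage-based applicability domain diagnostics.

    ``table`` has one row per record with columns: set, leverage,
    std_residual, structural_outlier (h > h*), response_outlier
    (|std residual| > 3).
    """

    table: pd.DataFrame
    h_star: float
    n_params: int


def q2_mae_loo(features: pd.DataFrame, y: Sequence[float]) -> tuple[float, float]:
    """LOO cross-validated Q^2 (= 1 - PRESS/TSS) and MAE for a fixed feature set."""
    yv = np.asarray(y, dtype=float)
    e = loo_residuals(features, yv)
    press = float(e @ e)
    tss = float(np.sum((yv - yv.mean()) ** 2))
    if tss == 0:
        raise ValueError("constant response: Q2_LOO undefined")
    return 1.0 - press / tss, float(np.mean(np.abs(e)))


def q2_mae_lco(
    dataset: MixtureDataset,
    features: pd.DataFrame,
    y: pd.Series,
    model_features: Sequence[str],
) -> tuple[float, float, list[str]]:
    """Leave-chemical-out cross-validation, pooled over all chemicals.

    For each unique chemical (union of HBA and HBD ids in ``dataset``),
    all records containing it are removed, coefficients are refit on the
    remainder (same feature subset) and the removed records predicted.
    Records containing two chemicals are held out once per chemical and
    contribute once per hold-out to the pooled vector. A chemical whose
    removal leaves too few records to refit is skipped and reported.
    """
    cols = list(model_features)
    chemicals = sorted({r.comp1_id for r in dataset} | {r.comp2_id for r in dataset})
    obs, pred, skipped = [], [], []
    for chem in chemicals:
        out_ids = [r.record_id for r in dataset if chem in (r.comp1_id, r.comp2_id)]
        in_ids = [r.record_id for r in dataset if chem not in (r.comp1_id, r.comp2_id)]
        if len(in_ids) < len(cols) + 2:
            skipped.append(chem)
            continue
        model = fit_ols(features.loc[in_ids, cols], y.loc[in_ids])
        p = model.predict(features.loc[out_ids, cols])
        obs.extend(y.loc[out_ids].tolist())
        pred.extend(p.tolist())
    obs_v = np.asarray(obs)
    pred_v = np.asarray(pred)
    sse = float(np.sum((obs_v - pred_v) ** 2))
    sst = float(np.sum((obs_v - obs_v.mean()) ** 2))
    if sst == 0:
        raise ValueError("constant pooled response: Q2_LCO undefined")
    return 1.0 - sse / sst, float(np.mean(np.abs(obs_v - pred_v))), skipped


def r2_pred(y_obs: Sequence[float], y_pred: Sequence[float], train_mean: float) -> float:
    """Variance explained for external prediction.

    ``1 - SSE / sum((y_obs - train_mean)^2)``; the reference point is the
    *training* response mean, so a model no better than the training mean
    scores 0 and a worse one goes negative.
    """
    yo = np.asarray(y_obs, dtype=float)
    yp = np.asarray(y_pred, dtype=float)
    if yo.size == 0 or yo.size != yp.size:
        raise ValueError("observed and predicted vectors must be non-empty and equal length")
    denom = float(np.sum((yo - train_mean) ** 2))
    if denom == 0:
        raise ValueError("zero denominator: observations all equal the training mean")
    return 1.0 - float(np.sum((yo - yp) ** 2)) / denom


def percent_rd(y_obs: Sequence[float], y_pred: Sequence[float]) -> np.ndarray:
    """Per-record signed relative deviation, 100*(pred - obs)/obs."""
    yo = np.asarray(y_obs, dtype=float)
    yp = np.asarray(y_pred, dtype=float)
    if np.any(yo == 0):
        raise ValueError("zero observation: relative deviation undefined")
    return 100.0 * (yp - yo) / yo


def aard(y_obs: Sequence[float], y_pred: Sequence[float]) -> float:
    """Absolute average relative deviation in percent."""
    return float(np.mean(np.abs(percent_rd(y_obs, y_pred))))


def _minmax(v: np.ndarray) -> np.ndarray:
    lo, hi = v.min(), v.max()
    if hi == lo:
        raise ValueError("constant vector: rm2 metrics undefined")
    return (v - lo) / (hi - lo)


def _r0_squared(y: np.ndarray, x: np.ndarray) -> float:
    """R^2 of the through-origin regression of y on x."""
    k = float(x @ y) / float(x @ x)
    sse = float(np.sum((y - k * x) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - sse / sst


def rm2_metrics(y_obs: Sequence[float], y_pred: Sequence[float]) -> dict[str, float]:
    """Scaled rm^2 external-validation metrics (Roy-type).

    Both vectors are min-max scaled to [0, 1]. ``r2`` is the squared
    Pearson correlation; ``r0^2`` (observed regressed on predicted) and
    ``r0'^2`` (predicted on observed) force a zero intercept. Then
    ``rm2 = r2 * (1 - sqrt(r2 - r0^2))`` and analogously for the primed
    variant; ``delta_rm2`` is their absolute difference and ``rm2_avg``
    their mean. Tiny negative square-root arguments from floating point
    are clamped at zero.
    """
    yo = _minmax(np.asarray(y_obs, dtype=float))
    yp = _minmax(np.asarray(y_pred, dtype=float))
    if yo.size < 3:
        raise ValueError("need at least 3 points for rm2 metrics")
    r = np.corrcoef(yo, yp)[0, 1]
    r2 = float(r * r)
    r0sq = _r0_squared(yo, yp)
    r0sq_prime = _r0_squared(yp, yo)
    rm2 = r2 * (1.0 - math.sqrt(max(r2 - r0sq, 0.0)))
    rm2_prime = r2 * (1.0 - math.sqrt(max(r2 - r0sq_prime, 0.0)))
    return {
        "rm2": rm2,
        "rm2_prime": rm2_prime,
        "rm2_avg": 0.5 * (rm2 + rm2_prime),
        "delta_rm2": abs(rm2 - rm2_prime),
    }


def y_randomization(
    features: pd.DataFrame,
    y: Sequence[float],
    n_runs: int = 1000,
    rng_seed: int = 0,
) -> RandomizationReport:
    """Chance-correlation check by response scrambling.

    The response vector is permuted ``n_runs`` times; a model with the
    same feature subset is refit on each permutation and its R^2 recorded.
    ``cRp^2 = R * sqrt(R^2 - mean(Rr^2))`` (clamped at 0), where R is the
    original model's multiple correlation coefficient. Values close to 1
    indicate the original correlation is not a chance artifact.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    yv = np.asarray(y, dtype=float)
    rng = np.random.default_rng(rng_seed)
    base = fit_ols(features, yv)
    r2s = np.empty(n_runs)
    for i in range(n_runs):
        r2s[i] = fit_ols(features, rng.permutation(yv)).r2
    mean_r2 = float(r2s.mean())
    r = math.sqrt(max(base.r2, 0.0))
    crp2 = r * math.sqrt(max(base.r2 - mean_r2, 0.0))
    return RandomizationReport(
        n_runs=n_runs, model_r=r, mean_randomized_r2=mean_r2, crp2=crp2
    )


def williams(
    model: LinearModel,
    train_features: pd.DataFrame,
    train_y: Sequence[float],
    **other_sets: tuple[pd.DataFrame, Sequence[float]],
) -> ADReport:
    """Leverage / standardized-residual applicability-domain diagnostics.

    Training leverages are the hat-matrix diagonal; rows of any other set
    are evaluated against the *training* (X'X)^-1. The warning leverage is
    ``h* = 3(p+1)/n_train``; standardized residuals divide by the sample
    standard deviation of the training residuals. Flags: structural
    outlier if h > h*, response outlier if |standardized residual| > 3.
    """
    cols = list(model.feature_names)
    Xtr = train_features[cols]
    ytr = np.asarray(train_y, dtype=float)
    n, p = len(Xtr), len(cols)
    Xd = np.column_stack([np.ones(n), Xtr.to_numpy(dtype=float)])
    XtX_inv = np.linalg.inv(Xd.T @ Xd)
    resid_tr = ytr - model.predict(Xtr)
    sd = float(np.std(resid_tr, ddof=1))
    h_star = 3.0 * (p + 1) / n

    def _rows(X: pd.DataFrame, y: Sequence[float], label: str) -> pd.DataFrame:
        Xa = np.column_stack([np.ones(len(X)), X[cols].to_numpy(dtype=float)])
        h = np.einsum("ij,jk,ik->i", Xa, XtX_inv, Xa)
        std_res = (np.asarray(y, dtype=float) - model.predict(X)) / sd
        return pd.DataFrame(
            {
                "set": label,
                "leverage": h,
                "std_residual": std_res,
                "structural_outlier": h > h_star,
                "response_outlier": np.abs(std_res) > 3.0,
            },
            index=X.index,
        )

    frames = [_rows(Xtr, ytr, "train")]
    for label, (X, y) in other_sets.items():
        frames.append(_rows(X, y, label))
    return ADReport(table=pd.concat(frames), h_star=h_star, n_params=p + 1)


def validate_model(
    model: LinearModel,
    dataset_train: MixtureDataset,
    train_features: pd.DataFrame,
    train_y: pd.Series,
    external_sets: dict[str, tuple[pd.DataFrame, pd.Series]] | None = None,
) -> ValidationReport:
    """Assemble the full battery for a fitted model.

    ``external_sets`` maps a set label (e.g. ``"test"``, ``"ext"``) to its
    (feature matrix, response) pair.
    """
    cols = list(model.feature_names)
    report = ValidationReport()
    report.q2_loo, report.mae_loo = q2_mae_loo(train_features[cols], train_y)
    report.q2_lco, report.mae_lco, report.lco_skipped = q2_mae_lco(
        dataset_train, train_features, train_y, cols
    )
    pred_tr = model.predict(train_features)
    report.aard_train = aard(train_y, pred_tr)
    loo_pred = np.asarray(train_y, dtype=float) - loo_residuals(train_features[cols], train_y)
    report.rm2["loo"] = rm2_metrics(train_y, loo_pred)
    train_mean = float(np.mean(train_y))
    for label, (X, y) in (external_sets or {}).items():
        pred = model.predict(X)
        report.external[label] = {
            "r2_pred": r2_pred(y, pred, train_mean),
            "mae": float(np.mean(np.abs(np.asarray(y, dtype=float) - pred))),
            "aard": aard(y, pred),
        }
        report.rm2[label] = rm2_metrics(y, pred)
    return report
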