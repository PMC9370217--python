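"""Intelligent-consensus prediction over multiple fitted linear models.

Four strategies combine the predictions of >= 2 individual models:

* **CM0** — unweighted mean of all member predictions.
* **CM1** — unweighted mean over the *qualified* members only.
* **CM2** — weighted mean over qualified members; each member's weight is
  proportional to the reciprocal of its mean absolute error over the k
  nearest training records (Euclidean distance in that member's
  standardized feature space).
* **CM3** — per-record single best member: the qualified member with the
  smallest neighborhood MAE.

A member is *qualified* for a record when the record falls inside the
member's leverage applicability domain (h <= h* computed from that
member's training design). Records with no qualified member fall back to
CM0 and are flagged in the trace. The qualification rule and the
neighborhood error estimate are this package's own concrete choices for
the consensus machinery; the strategy layer is pluggable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .linear import LinearModel

Strategy = Literal["CM0", "CM1", "CM2", "CM3"]

_EPS_MAE = 1e-12


@dataclass
class ConsensusMember:
    """One individual model plus the training data it was fitted on."""

    model: LinearModel
    train_features: pd.DataFrame  # must contain the model's feature columns
    train_y: pd.Series

    def __post_init__(self) -> None:
        cols = list(self.model.feature_names)
        X = self.train_features[cols].to_numpy(dtype=float)
        self._cols = cols
        self._mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        self._sd = np.where(sd == 0.0, 1.0, sd)
        self._Z = (X - self._mean) / self._sd
        n = X.shape[0]
        Xd = np.column_stack([np.ones(n), X])
        self._XtX_inv = np.linalg.inv(Xd.T @ Xd)
        self.h_star = 3.0 * (len(cols) + 1) / n
        self._train_abs_err = np.abs(
            np.asarray(self.train_y, dtype=float) - self.model.predict(self.train_features)
        )

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        return self.model.predict(features)

    def leverage(self, features: pd.DataFrame) -> np.ndarray:
        Xa = np.column_stack(
            [np.ones(len(features)), features[self._cols].to_numpy(dtype=float)]
        )
        return np.einsum("ij,jk,ik->i", Xa, self._XtX_inv, Xa)

    def neighborhood_mae(self, features: pd.DataFrame, k: int) -> np.ndarray:
        """Mean |training error| over the k nearest training records."""
        Z = (features[self._cols].to_numpy(dtype=float) - self._mean) / self._sd
        k = min(k, self._Z.shape[0])
        d2 = ((Z[:, None, :] - self._Z[None, :, :]) ** 2).sum(axis=2)
        nearest = np.argpartition(d2, k - 1, axis=1)[:, :k]
        return self._train_abs_err[nearest].mean(axis=1)


def consensus_predict(
    members: Sequence[ConsensusMember],
    feature_matrices: Sequence[pd.DataFrame],
    strategy: Strategy = "CM0",
    k: int = 10,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Consensus predictions plus a per-record trace.

    ``feature_matrices[m]`` holds the rows to score in model *m*'s feature
    space; all matrices must be row-aligned. The trace records, per
    record, which members qualified, the weights (CM2) or chosen member
    (CM3), and whether the CM0 fallback was used.
    """
    if len(members) < 2:
        raise ValueError("consensus requires at least 2 models")
    if len(feature_matrices) != len(members):
        raise ValueError("one feature matrix per member required")
    if k < 1:
        raise ValueError("k must be >= 1")
    n = len(feature_matrices[0])
    preds = np.vstack([m.predict(X) for m, X in zip(members, feature_matrices)])
    qualified = np.vstack(
        [m.leverage(X) <= m.h_star for m, X in zip(members, feature_matrices)]
    )
    if strategy == "CM0":
        out = preds.mean(axis=0)
        trace = pd.DataFrame(
            {"strategy": "CM0", "n_qualified": qualified.sum(axis=0), "fallback": False},
            index=feature_matrices[0].index,
        )
        return out, trace

    nb_mae = np.vstack(
        [m.neighborhood_mae(X, k) for m, X in zip(members, feature_matrices)]
    )
    out = np.empty(n)
    rows = []
    for i in range(n):
        q = np.flatnonzero(qualified[:, i])
        fallback = q.size == 0
        if fallback:
            out[i] = preds[:, i].mean()
            rows.append({"strategy": strategy, "n_qualified": 0, "fallback": True,
                         "chosen": None, "weights": None})
            continue
        if strategy == "CM1":
            out[i] = preds[q, i].mean()
            rows.append({"strategy": "CM1", "n_qualified": q.size, "fallback": False,
                         "chosen": None, "weights": None})
        elif strategy == "CM2":
            w = 1.0 / np.maximum(nb_mae[q, i], _EPS_MAE)
            w = w / w.sum()
            out[i] = float(w @ preds[q, i])
            rows.append({"strategy": "CM2", "n_qualified": q.size, "fallback": False,
                         "chosen": None, "weights": dict(zip(q.tolist(), w.tolist()))})
        elif strategy == "CM3":
            best = q[np.argmin(nb_mae[q, i])]
            out[i] = preds[best, i]
            rows.append({"strategy": "CM3", "n_qualified": q.size, "fallback": False,
                         "chosen": int(best), "weights": None})
        else:
            raise ValueError(f"unknown strategy '{strategy}'")
    trace = pd.DataFrame(rows, index=feature_matrices[0].index)
    return out, trace


class ConsensusPredictor:
    """Convenience object bundling members and a strategy.

    Not a scikit-learn estimator: the members arrive already fitted, each
    with its own feature space, so there is nothing to ``fit``.
    """

    def __init__(self, members: Sequence[ConsensusMember], strategy: Strategy = "CM0", k: int = 10):
        if len(members) < 2:
            raise ValueError("consensus requires at least 2 models")
        self.members = list(members)
        self.strategy = strategy
        self.k = k

    def predict(self, feature_matrices: Sequence[pd.DataFrame]) -> np.ndarray:
        out, _ = consensus_predict(self.members, feature_matrices, self.strategy, self.k)
        return out

    def predict_with_trace(self, feature_matrices: Sequence[pd.DataFrame]):
        return consensus_predict(self.members, feature_matrices, self.strategy, self.k)
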