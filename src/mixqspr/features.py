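"""Weighted-mixture (WM) descriptor matrices for binary mixtures.

Per-component descriptors (precomputed externally, e.g. Dragon-style
0D-2D descriptors) are combined with the molar fractions into mixture
descriptors:

    D_pmix = x1 * D1 + x2 * D2
    D_nmix = |x1 * D1 - x2 * D2|

Method-1 emits only the ``*_pmix`` columns, Method-2 both ``*_pmix`` and
``*_nmix``. The measuring temperature and the two halide indicator flags
are always appended as additional candidate variables.

:class:`VarianceCorrelationFilter` prunes near-constant and highly
intercorrelated columns; fitted on the training rows only, it applies the
surviving column list to any other set, preventing information leakage.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .data import MixtureDataset
from .errors import SchemaError, UnknownComponentError

AUX_COLUMNS = ["temperature", "cl_flag", "br_flag"]


class ComponentDescriptorTable:
    """Named descriptor vectors per component id.

    Wraps a DataFrame indexed by component id, one column per descriptor.
    All values must be finite; every component referenced by a dataset must
    be present.
    """

    def __init__(self, frame: pd.DataFrame):
        if frame.index.has_duplicates:
            raise SchemaError("duplicate component_id in descriptor table", field="component_id")
        values = frame.to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            bad = frame.columns[np.argwhere(~np.isfinite(values))[0][1]]
            raise SchemaError("non-finite descriptor value", field=str(bad))
        self.frame = frame.astype(float)

    @property
    def descriptor_names(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def component_ids(self) -> list[str]:
        return list(self.frame.index)

    def vector(self, component_id: str) -> pd.Series:
        if component_id not in self.frame.index:
            raise UnknownComponentError(component_id)
        return self.frame.loc[component_id]

    @classmethod
    def from_csv(cls, path: str | Path) -> "ComponentDescriptorTable":
        frame = pd.read_csv(path)
        if frame.columns[0] != "component_id":
            raise SchemaError("first column must be 'component_id'", field="component_id")
        return cls(frame.set_index("component_id"))

    def to_csv(self, path: str | Path) -> None:
        self.frame.rename_axis("component_id").to_csv(path)


def pmix(d1: float, d2: float, x1: float, x2: float) -> float:
    """Molar-fraction-weighted sum descriptor: ``x1*d1 + x2*d2``."""
    return x1 * d1 + x2 * d2


def nmix(d1: float, d2: float, x1: float, x2: float) -> float:
    """Molar-fraction-weighted absolute-difference descriptor: ``|x1*d1 - x2*d2|``."""
    return abs(x1 * d1 - x2 * d2)


class WMFeaturizer(BaseEstimator, TransformerMixin):
    """Stateless transformer building the WM design matrix for a dataset.

    Parameters
    ----------
    descriptor_table : ComponentDescriptorTable
    method : {1, 2}
        Method-1: ``*_pmix`` columns only. Method-2: ``*_pmix`` and
        ``*_nmix``. Temperature and the Cl/Br indicators are always
        appended.
    """

    def __init__(self, descriptor_table: ComponentDescriptorTable | None = None, method: int = 1):
        self.descriptor_table = descriptor_table
        self.method = method

    def fit(self, X: MixtureDataset, y=None) -> "WMFeaturizer":
        if self.method not in (1, 2):
            raise ValueError(f"method must be 1 or 2, got {self.method}")
        if self.descriptor_table is None:
            raise ValueError("descriptor_table is required")
        self.n_features_in_ = len(self.descriptor_table.descriptor_names)
        return self

    def transform(self, X: MixtureDataset) -> pd.DataFrame:
        check_is_fitted(self, "n_features_in_")
        table = self.descriptor_table
        names = table.descriptor_names
        d = table.frame
        rows = []
        for r in X:
            v1 = d.loc[r.comp1_id].to_numpy() if r.comp1_id in d.index else None
            if v1 is None:
                raise UnknownComponentError(r.comp1_id)
            if r.comp2_id not in d.index:
                raise UnknownComponentError(r.comp2_id)
            v2 = d.loc[r.comp2_id].to_numpy()
            row = {}
            p = r.x1 * v1 + r.x2 * v2
            for name, val in zip(names, p):
                row[f"{name}_pmix"] = val
            if self.method == 2:
                n = np.abs(r.x1 * v1 - r.x2 * v2)
                for name, val in zip(names, n):
                    row[f"{name}_nmix"] = val
            row["temperature"] = r.temperature
            row["cl_flag"] = float(r.cl_flag)
            row["br_flag"] = float(r.br_flag)
            rows.append(row)
        return pd.DataFrame(rows, index=X.record_ids, dtype=float)


def build_features(
    dataset: MixtureDataset,
    table: ComponentDescriptorTable,
    method: int = 1,
) -> pd.DataFrame:
    """WM feature matrix aligned to ``dataset`` (rows indexed by record id)."""
    return WMFeaturizer(table, method=method).fit(dataset).transform(dataset)


class VarianceCorrelationFilter(BaseEstimator, TransformerMixin):
    """Drop near-constant, then highly intercorrelated, columns.

    A column is dropped iff its variance is strictly below
    ``variance_cutoff``; then column pairs are scanned in input order and
    the *later* column of any pair with ``|r| > correlation_cutoff`` is
    dropped (the earlier column survives). Both rules are deterministic.

    ``allow_constant_flags=True`` exempts the auxiliary indicator columns
    (``cl_flag``/``br_flag``) from the variance rule, for datasets where a
    constant flag should still be carried through.
    """

    def __init__(
        self,
        variance_cutoff: float = 0.001,
        correlation_cutoff: float = 0.95,
        allow_constant_flags: bool = False,
    ):
        self.variance_cutoff = variance_cutoff
        self.correlation_cutoff = correlation_cutoff
        self.allow_constant_flags = allow_constant_flags

    def fit(self, X: pd.DataFrame, y=None) -> "VarianceCorrelationFilter":
        if len(X) < 2:
            raise ValueError("need at least 2 rows to estimate variances")
        exempt = {"cl_flag", "br_flag"} if self.allow_constant_flags else set()
        variances = X.var(axis=0, ddof=1)
        kept = [
            c
            for c in X.columns
            if c in exempt or variances[c] >= self.variance_cutoff
        ]
        # pairwise scan in column order; later member of a correlated pair drops
        values = X[kept].to_numpy(dtype=float)
        std = values.std(axis=0, ddof=1)
        survivors: list[int] = []
        for j in range(len(kept)):
            drop = False
            for i in survivors:
                if std[i] == 0.0 or std[j] == 0.0:
                    continue
                r = np.corrcoef(values[:, i], values[:, j])[0, 1]
                if abs(r) > self.correlation_cutoff:
                    drop = True
                    break
            if not drop:
                survivors.append(j)
        self.kept_columns_ = [kept[j] for j in survivors]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "kept_columns_")
        return X[self.kept_columns_]


def filter_features(
    matrix: pd.DataFrame,
    variance_cutoff: float = 0.001,
    correlation_cutoff: float = 0.95,
    allow_constant_flags: bool = False,
) -> pd.DataFrame:
    """One-shot variance + correlation pruning of a feature matrix."""
    flt = VarianceCorrelationFilter(variance_cutoff, correlation_cutoff, allow_constant_flags)
    return flt.fit_transform(matrix)


def write_features(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.rename_axis("record_id").to_csv(path)
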