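"""Model-building campaign: splits x descriptor methods x scorings.

The workflow: carve an external validation set off the full dataset once
(compounds-out, seed 3, interval 4, by default), enumerate every
admissible mixtures-out and compounds-out split of the remaining modeling
set (seed, interval <= 6), and for each (split, descriptor method,
scoring) cell prune the training feature matrix, run forward selection
and compute the full validation battery. Cells are ranked by the mean of
Q^2_LOO, Q^2_LCO and R^2_Pred on the test set (ties by MAE_test
ascending) and the top N distinct (partition, feature set) pairs are
retained.

Everything is a pure function of (dataset, descriptor table, config):
reruns reproduce the ranked list exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .data import MixtureDataset
from .errors import MixQSPRError
from .features import ComponentDescriptorTable, VarianceCorrelationFilter, build_features
from .linear import LinearModel, sfs_select
from .splitting import DataSplit, SplitSpec, co_split, enumerate_valid_splits
from .validation import ValidationReport, validate_model


@dataclass
class CampaignConfig:
    schemes: tuple[str, ...] = ("MO", "CO")
    max_seed: int = 6
    max_interval: int = 6
    methods: tuple[int, ...] = (1, 2)
    scorings: tuple[str, ...] = ("R2", "NMAE", "NMPD", "R2_cv5", "R2_cv10")
    mae_reduction: float = 0.05
    variance_cutoff: float = 0.001
    correlation_cutoff: float = 0.95
    top_n: int = 15
    cv_seed: int = 0
    external_split: SplitSpec | None = SplitSpec("CO", 3, 4)
    max_features: int | None = None


@dataclass
class CampaignResult:
    cell_id: str
    split: DataSplit
    method: int
    scoring: str
    model: LinearModel
    report: ValidationReport

    @property
    def score(self) -> float:
        """Mean of Q^2_LOO, Q^2_LCO and R^2_Pred(test)."""
        stats = (
            self.report.q2_loo,
            self.report.q2_lco,
            self.report.external.get("test", {}).get("r2_pred", math.nan),
        )
        return float(np.mean(stats))

    @property
    def mae_test(self) -> float:
        return self.report.external.get("test", {}).get("mae", math.nan)


@dataclass
class CampaignOutput:
    results: list[CampaignResult]
    failures: list[tuple[str, str]]
    external_ids: tuple[str, ...]
    ranked: list[CampaignResult] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for res in self.ranked or self.results:
            d = res.report.to_dict()
            rows.append(
                {
                    "cell_id": res.cell_id,
                    "scheme": res.split.spec.scheme,
                    "seed": res.split.spec.seed,
                    "interval": res.split.spec.interval,
                    "method": res.method,
                    "scoring": res.scoring,
                    "n_train": res.split.n_train,
                    "n_test": res.split.n_test,
                    "n_features": res.model.n_features,
                    "features": ";".join(res.model.feature_names),
                    "score": res.score,
                    **d,
                }
            )
        return pd.DataFrame(rows)


def final_score(model_stats: Sequence[float]) -> float:
    """Mean of (Q^2_LOO, Q^2_LCO, R^2_Pred test, R^2_Pred external)."""
    stats = [float(s) for s in model_stats]
    if len(stats) != 4:
        raise ValueError("expected exactly four statistics")
    return float(np.mean(stats))


def rank_models(results: Sequence[CampaignResult]) -> list[CampaignResult]:
    """Descending by score; ties broken by MAE_test ascending.

    Results missing any of the three statistics are excluded.
    """
    usable = [
        r
        for r in results
        if math.isfinite(r.score) and math.isfinite(r.mae_test)
    ]
    return sorted(usable, key=lambda r: (-r.score, r.mae_test, r.cell_id))


def run_campaign(
    dataset: MixtureDataset,
    descriptor_table: ComponentDescriptorTable,
    config: CampaignConfig | None = None,
) -> CampaignOutput:
    config = config or CampaignConfig()

    if config.external_split is not None:
        ext = co_split(dataset, config.external_split.seed, config.external_split.interval)
        # the CO selection goes to the carved-off external validation set
        modeling = dataset.subset(ext.train_ids)
        external = dataset.subset(ext.test_ids)
        external_ids = ext.test_ids
    else:
        modeling, external, external_ids = dataset, None, ()

    y_all = modeling.sigma()
    results: list[CampaignResult] = []
    failures: list[tuple[str, str]] = []
    for method in config.methods:
        feats = build_features(modeling, descriptor_table, method=method)
        feats_ext = (
            build_features(external, descriptor_table, method=method)
            if external is not None and len(external)
            else None
        )
        for scheme in config.schemes:
            splits = enumerate_valid_splits(
                modeling, scheme, config.max_seed, config.max_interval
            )
            for sp in splits:
                cell_id = f"{scheme}-s{sp.spec.seed}i{sp.spec.interval}-m{method}"
                for scoring in config.scorings:
                    cid = f"{cell_id}-{scoring}"
                    try:
                        results.append(
                            _run_cell(
                                modeling, feats, feats_ext, external, y_all, sp,
                                method, scoring, config, cid,
                            )
                        )
                    except (MixQSPRError, ValueError) as err:
                        failures.append((cid, str(err)))

    ranked_all = rank_models(results)
    seen: set[tuple[frozenset[str], tuple[str, ...]]] = set()
    top: list[CampaignResult] = []
    for res in ranked_all:
        key = (frozenset(res.split.test_ids), tuple(res.model.feature_names))
        if key in seen:
            continue
        seen.add(key)
        top.append(res)
        if len(top) >= config.top_n:
            break
    return CampaignOutput(
        results=results, failures=failures, external_ids=tuple(external_ids), ranked=top
    )


def _run_cell(
    modeling: MixtureDataset,
    feats: pd.DataFrame,
    feats_ext: pd.DataFrame | None,
    external: MixtureDataset | None,
    y_all: pd.Series,
    sp: DataSplit,
    method: int,
    scoring: str,
    config: CampaignConfig,
    cell_id: str,
) -> CampaignResult:
    train_ids = list(sp.train_ids)
    test_ids = list(sp.test_ids)
    flt = VarianceCorrelationFilter(
        config.variance_cutoff, config.correlation_cutoff
    ).fit(feats.loc[train_ids])
    Xtr = flt.transform(feats.loc[train_ids])
    ytr = y_all.loc[train_ids]
    model = sfs_select(
        Xtr,
        ytr,
        scoring=scoring,
        mae_reduction=config.mae_reduction,
        max_features=config.max_features,
        cv_seed=config.cv_seed,
    )
    ext_sets = {"test": (flt.transform(feats.loc[test_ids]), y_all.loc[test_ids])}
    if feats_ext is not None and external is not None:
        ext_sets["ext"] = (flt.transform(feats_ext), external.sigma())
    report = validate_model(
        model, modeling.subset(train_ids), Xtr, ytr, external_sets=ext_sets
    )
    return CampaignResult(
        cell_id=cell_id, split=sp, method=method, scoring=scoring, model=model, report=report
    )
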