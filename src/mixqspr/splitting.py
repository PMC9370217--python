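"""Deterministic mixtures-out (MO) and compounds-out (CO) data splitting.

Random train/test division is unreliable for mixture QSPR: the same
mixture (or the same chemical) on both sides of the partition leaks
information and inflates apparent predictivity. The two schemes here keep
whole mixtures (MO) or whole chemicals (CO) on one side.

Both schemes are driven by two positive integers, ``seed`` and
``interval``: unique mixtures (or per-role chemicals) are sorted by
occurrence count descending (lexicographic ascending tie-break) and the
entries at 1-based positions ``seed, seed+interval, seed+2*interval, ...``
are selected for the test set. Identical inputs always produce identical
partitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence, TypeVar

from .data import MixtureDataset, mixture_key, occurrence_counts
from .errors import DegenerateSplitError

T = TypeVar("T")

Scheme = Literal["MO", "CO"]


@dataclass(frozen=True)
class SplitSpec:
    scheme: Scheme
    seed: int
    interval: int

    def __post_init__(self) -> None:
        if self.seed < 1 or self.interval < 1:
            raise ValueError("seed and interval must be >= 1")
        if self.scheme not in ("MO", "CO"):
            raise ValueError(f"unknown scheme '{self.scheme}'")


@dataclass(frozen=True)
class DataSplit:
    """Train/test partition with provenance."""

    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    spec: SplitSpec
    selected_keys: tuple[str, ...] = field(default_factory=tuple)

    @property
    def n_train(self) -> int:
        return len(self.train_ids)

    @property
    def n_test(self) -> int:
        return len(self.test_ids)


def select_by_seed_interval(sorted_keys: Sequence[T], seed: int, interval: int) -> list[T]:
    """Elements at 1-based positions seed, seed+interval, seed+2*interval, ...

    A seed beyond the end of the list selects nothing.
    """
    if seed < 1 or interval < 1:
        raise ValueError("seed and interval must be >= 1")
    return [sorted_keys[i] for i in range(seed - 1, len(sorted_keys), interval)]


def _partition(dataset: MixtureDataset, test_ids: set[str], spec: SplitSpec,
               selected: Sequence[str]) -> DataSplit:
    train = tuple(r.record_id for r in dataset if r.record_id not in test_ids)
    test = tuple(r.record_id for r in dataset if r.record_id in test_ids)
    if not train or not test:
        raise DegenerateSplitError(
            f"{spec.scheme} split (seed={spec.seed}, interval={spec.interval}) "
            f"leaves {len(train)} training and {len(test)} test records"
        )
    return DataSplit(train_ids=train, test_ids=test, spec=spec, selected_keys=tuple(selected))


def mo_split(dataset: MixtureDataset, seed: int, interval: int) -> DataSplit:
    """Mixtures-out split: whole mixtures (pair + ratio) go to the test set."""
    spec = SplitSpec("MO", seed, interval)
    counts = occurrence_counts(dataset, by="mixture")
    if len(counts) < 2:
        raise DegenerateSplitError("need at least 2 unique mixtures for an MO split")
    selected = set(select_by_seed_interval([k for k, _ in counts], seed, interval))
    test_ids = {r.record_id for r in dataset if str(mixture_key(r)) in selected}
    return _partition(dataset, test_ids, spec, sorted(selected))


def co_split(dataset: MixtureDataset, seed: int, interval: int) -> DataSplit:
    """Compounds-out split: selected chemicals never appear in training.

    Selection runs independently, with the same (seed, interval), on the
    occurrence-sorted component-1 (HBA) list and on the component-2 (HBD)
    list; every record containing a selected chemical in its role goes to
    the test set. A chemical occurring in both roles is tracked per role.
    """
    spec = SplitSpec("CO", seed, interval)
    c1 = occurrence_counts(dataset, by="component1")
    c2 = occurrence_counts(dataset, by="component2")
    if len(c1) < 2 or len(c2) < 2:
        raise DegenerateSplitError("need at least 2 unique chemicals in each role for a CO split")
    sel1 = set(select_by_seed_interval([k for k, _ in c1], seed, interval))
    sel2 = set(select_by_seed_interval([k for k, _ in c2], seed, interval))
    test_ids = {
        r.record_id for r in dataset if r.comp1_id in sel1 or r.comp2_id in sel2
    }
    selected = sorted(f"comp1:{c}" for c in sel1) + sorted(f"comp2:{c}" for c in sel2)
    return _partition(dataset, test_ids, spec, selected)


def split(dataset: MixtureDataset, spec: SplitSpec) -> DataSplit:
    """Dispatch on the scheme of ``spec``."""
    fn = mo_split if spec.scheme == "MO" else co_split
    return fn(dataset, spec.seed, spec.interval)


def enumerate_valid_splits(
    dataset: MixtureDataset,
    scheme: Scheme,
    max_seed: int = 6,
    max_interval: int = 6,
    min_test_fraction: float = 0.15,
) -> list[DataSplit]:
    """All admissible (seed, interval) splits up to the given maxima.

    A split is retained iff the training set is strictly larger than the
    test set and the test set holds at least ``min_test_fraction`` of the
    training size. Duplicate partitions (identical test-id sets) collapse
    to the lexicographically smallest (seed, interval).
    """
    seen: dict[frozenset[str], DataSplit] = {}
    order: list[frozenset[str]] = []
    for seed in range(1, max_seed + 1):
        for interval in range(1, max_interval + 1):
            try:
                s = split(dataset, SplitSpec(scheme, seed, interval))
            except DegenerateSplitError:
                continue
            if not (s.n_train > s.n_test and s.n_test >= min_test_fraction * s.n_train):
                continue
            key = frozenset(s.test_ids)
            if key not in seen:
                seen[key] = s
                order.append(key)
    return [seen[k] for k in order]


def export_split(split_: DataSplit, csv_path, json_path=None) -> None:
    """Two-column CSV (record_id, set) plus an optional JSON sidecar."""
    import json
    from pathlib import Path

    import pandas as pd

    rows = [{"record_id": rid, "set": "train"} for rid in split_.train_ids]
    rows += [{"record_id": rid, "set": "test"} for rid in split_.test_ids]
    pd.DataFrame(rows).to_csv(csv_path, index=False)
    if json_path is not None:
        sidecar = {
            "scheme": split_.spec.scheme,
            "seed": split_.spec.seed,
            "interval": split_.spec.interval,
            "selected_keys": list(split_.selected_keys),
            "n_train": split_.n_train,
            "n_test": split_.n_test,
        }
        Path(json_path).write_text(json.dumps(sidecar, indent=2))
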