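"""Data model and I/O for binary-mixture property datasets.

A *mixture record* is one measurement of a binary deep eutectic solvent
(DES): the hydrogen-bond acceptor (HBA, component 1; for quaternary
ammonium salts only the cation carries descriptors, the halide anion is
encoded by two indicator flags), the hydrogen-bond donor (HBD, component
2), their molar fractions, the measuring temperature in kelvin and the
measured response (surface tension in mN/m).

Mixture *identity* is the component pair plus the molar ratio: records of
the same DES at different temperatures share a :class:`MixtureKey`, while
the same pair at a different ratio is a different mixture.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Iterator, Literal

import pandas as pd

from .errors import SchemaError

#: Canonical CSV column order for mixture datasets.
DATASET_COLUMNS = [
    "record_id",
    "comp1_id",
    "comp1_smiles",
    "comp2_id",
    "comp2_smiles",
    "x1",
    "x2",
    "temperature_K",
    "cl_flag",
    "br_flag",
    "sigma_mN_per_m",
]

_FRACTION_TOL = 1e-9
_RATIO_TOL = 1e-6


@dataclass(frozen=True)
class MixtureRecord:
    """One measurement of a binary mixture.

    ``sigma`` may be ``None`` for prediction-only rows.
    """

    record_id: str
    comp1_id: str
    comp2_id: str
    smiles1: str
    smiles2: str
    x1: float
    x2: float
    temperature: float
    cl_flag: int
    br_flag: int
    sigma: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.x1 < 1.0):
            raise SchemaError(f"x1={self.x1} must lie strictly in (0, 1)", field="x1")
        if not (0.0 < self.x2 < 1.0):
            raise SchemaError(f"x2={self.x2} must lie strictly in (0, 1)", field="x2")
        if abs(self.x1 + self.x2 - 1.0) > _FRACTION_TOL:
            raise SchemaError(
                f"molar fractions must sum to 1 (got {self.x1 + self.x2})", field="x2"
            )
        if not self.temperature > 0:
            raise SchemaError(
                f"temperature={self.temperature} must be positive", field="temperature_K"
            )
        if self.sigma is not None and not self.sigma > 0:
            raise SchemaError(
                f"sigma={self.sigma} must be positive when present",
                field="sigma_mN_per_m",
            )
        for name in ("cl_flag", "br_flag"):
            if getattr(self, name) not in (0, 1):
                raise SchemaError(f"{name} must be 0 or 1", field=name)


@dataclass(frozen=True, order=True)
class MixtureKey:
    """Temperature-invariant identity of a mixture: pair + molar ratio."""

    comp1_id: str
    comp2_id: str
    ratio: str

    def __str__(self) -> str:  # used for lexicographic tie-breaks
        return f"{self.comp1_id}|{self.comp2_id}|{self.ratio}"


def canonical_ratio(x1: float, x2: float, tol: float = _RATIO_TOL) -> str:
    """Reduce molar fractions to a canonical ratio label.

    If ``x1`` is rational within ``tol`` the label is the lowest-term
    integer ratio ``"p:q"`` (e.g. x1=1/3 -> "1:2"); otherwise ``x1``
    rounded to 4 decimals. Candidate denominators are capped at 100 —
    ample for real molar ratios, and small enough that the rationality
    test can actually fail (every real number is within 1e-6 of *some*
    large-denominator fraction).
    """
    frac = Fraction(x1).limit_denominator(100)
    if abs(float(frac) - x1) <= tol and 0 < frac.numerator < frac.denominator:
        p = frac.numerator
        q = frac.denominator - frac.numerator
        return f"{p}:{q}"
    return f"{x1:.4f}"


def mixture_key(record: MixtureRecord) -> MixtureKey:
    """Identity key of the mixture a record belongs to (pure function)."""
    return MixtureKey(
        comp1_id=record.comp1_id,
        comp2_id=record.comp2_id,
        ratio=canonical_ratio(record.x1, record.x2),
    )


@dataclass
class MixtureDataset:
    """An ordered collection of validated :class:`MixtureRecord`."""

    records: list[MixtureRecord] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [r.record_id for r in self.records]
        if len(ids) != len(set(ids)):
            seen: set[str] = set()
            dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
            raise SchemaError(f"duplicate record_id '{dup}'", field="record_id")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[MixtureRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> MixtureRecord:
        return self.records[i]

    @property
    def record_ids(self) -> list[str]:
        return [r.record_id for r in self.records]

    def subset(self, record_ids: Iterable[str]) -> "MixtureDataset":
        """Records whose id is in ``record_ids``, original order preserved."""
        wanted = set(record_ids)
        return MixtureDataset(
            records=[r for r in self.records if r.record_id in wanted],
            provenance=self.provenance,
        )

    def sigma(self) -> pd.Series:
        """Response vector indexed by record id (rows without sigma excluded)."""
        data = {r.record_id: r.sigma for r in self.records if r.sigma is not None}
        return pd.Series(data, name="sigma_mN_per_m", dtype=float)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "record_id": r.record_id,
                "comp1_id": r.comp1_id,
                "comp1_smiles": r.smiles1,
                "comp2_id": r.comp2_id,
                "comp2_smiles": r.smiles2,
                "x1": r.x1,
                "x2": r.x2,
                "temperature_K": r.temperature,
                "cl_flag": r.cl_flag,
                "br_flag": r.br_flag,
                "sigma_mN_per_m": r.sigma,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=DATASET_COLUMNS)


def _parse_float(value, row: int, column: str) -> float:
    try:
        return float(value)
    except (TypeError, ValueError):
        raise SchemaError(f"non-numeric value '{value}'", row=row, field=column) from None


def load_dataset(path: str | Path, provenance: str | None = None) -> MixtureDataset:
    """Read a mixture dataset CSV, validating every row.

    The header must contain exactly the documented columns (comma
    separated, "." decimal, UTF-8). Row order is preserved.
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in DATASET_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")
    records = []
    for i, row in enumerate(frame.itertuples(index=False)):
        raw = dict(zip(frame.columns, row))
        sigma_raw = raw["sigma_mN_per_m"].strip()
        try:
            records.append(
                MixtureRecord(
                    record_id=raw["record_id"],
                    comp1_id=raw["comp1_id"],
                    comp2_id=raw["comp2_id"],
                    smiles1=raw["comp1_smiles"],
                    smiles2=raw["comp2_smiles"],
                    x1=_parse_float(raw["x1"], i, "x1"),
                    x2=_parse_float(raw["x2"], i, "x2"),
                    temperature=_parse_float(raw["temperature_K"], i, "temperature_K"),
                    cl_flag=int(_parse_float(raw["cl_flag"], i, "cl_flag")),
                    br_flag=int(_parse_float(raw["br_flag"], i, "br_flag")),
                    sigma=None if sigma_raw == "" else _parse_float(sigma_raw, i, "sigma_mN_per_m"),
                )
            )
        except SchemaError as err:
            if err.row is None:
                raise SchemaError(str(err.args[0]).split(" (field")[0], row=i, field=err.field) from None
            raise
    return MixtureDataset(records=records, provenance=provenance or str(path))


def write_dataset(dataset: MixtureDataset, path: str | Path) -> None:
    """Write a dataset to CSV in the canonical schema (round-trip safe)."""
    dataset.to_frame().to_csv(path, index=False)


def occurrence_counts(
    dataset: MixtureDataset,
    by: Literal["mixture", "component1", "component2"] = "mixture",
) -> list[tuple[str, int]]:
    """Occurrence counts of mixtures or per-role chemicals.

    Sorted by count descending; ties broken by ascending lexicographic key
    so that the ordering (and everything seeded from it, e.g. data splits)
    is deterministic. For ``by='mixture'`` the counts sum to the number of
    records.
    """
    if by == "mixture":
        keys = [str(mixture_key(r)) for r in dataset]
    elif by == "component1":
        keys = [r.comp1_id for r in dataset]
    elif by == "component2":
        keys = [r.comp2_id for r in dataset]
    else:  # pragma: no cover - guarded by Literal
        raise ValueError(f"unknown grouping '{by}'")
    counts: dict[str, int] = {}
    for k in keys:
        counts[k] = counts.get(k, 0) + 1
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
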