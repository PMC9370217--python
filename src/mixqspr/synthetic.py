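"""Synthetic binary-mixture datasets with known ground truth.

The generator emulates the statistical structure of a DES surface-tension
data bank: a library of HBA (salt cation) and HBD components with named
descriptor vectors, mixtures at fixed small-integer molar ratios, each
measured over a temperature grid, and a response generated from a known
linear model in weighted-mixture (WM) descriptor space plus Gaussian
noise. Constant and exactly collinear nuisance descriptors are injected
so the pruning stage has real work to do.

The ground truth lives in WM space: component-level descriptors are drawn
first and the response is computed from the derived ``*_pmix`` columns,
so the mixture-descriptor formulas are exercised on every record. The
generator makes no attempt to mimic hydrogen-bond physics — only the
data layout and noise structure the modeling pipeline assumes.

Defaults give 60 mixtures x 5 temperatures = 300 records spanning
278.15-358.15 K in 20 K steps, 5 informative among 30 descriptors,
1 mN/m measurement noise. The component library (25 HBA + 35 HBD) is
deliberately wide relative to the number of mixtures, mirroring real DES
data banks where each component appears in only a few mixtures: a small
library would make every component-level column (including the halide
flags) a partial proxy for the informative descriptors through
finite-library chance correlations, and exact support recovery would be
ill-posed by construction rather than by noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .data import MixtureDataset, MixtureRecord
from .features import ComponentDescriptorTable
from .linear import LinearModel


@dataclass
class SyntheticConfig:
    n_hba: int = 25
    n_hbd: int = 35
    n_mixtures: int = 60
    ratios: tuple[tuple[int, int], ...] = ((1, 1), (1, 2), (1, 3), (1, 4), (2, 1))
    temperatures: tuple[float, ...] = (278.15, 298.15, 318.15, 338.15, 358.15)
    n_descriptors: int = 30
    n_informative: int = 5
    true_coefficients: Sequence[float] | None = None  # drawn if None
    coef_magnitude: tuple[float, float] = (2.0, 6.0)
    beta_temperature: float = -0.1
    intercept: float = 70.0
    noise_sd: float = 1.0  # mN/m
    frac_constant: float = 0.1
    frac_collinear: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        n_nuisance = round(self.frac_constant * self.n_descriptors) + round(
            self.frac_collinear * self.n_descriptors
        )
        if self.n_informative > self.n_descriptors - n_nuisance:
            raise ValueError(
                "n_informative exceeds the number of clean (non-nuisance) descriptors"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_mixtures > self.n_hba * self.n_hbd * len(self.ratios):
            raise ValueError("n_mixtures exceeds the number of distinct (HBA, HBD, ratio) triples")


def generate(
    config: SyntheticConfig | None = None, **overrides
) -> tuple[MixtureDataset, ComponentDescriptorTable, LinearModel]:
    """Generate a dataset, its descriptor table and the ground-truth model.

    Bit-reproducible for a fixed config (all randomness flows from
    ``config.seed``). The returned :class:`LinearModel` holds the true
    intercept and the true coefficients on the informative ``*_pmix``
    columns plus ``temperature``.
    """
    if config is None:
        config = SyntheticConfig(**overrides)
    elif overrides:
        raise ValueError("pass either a config or keyword overrides, not both")
    rng = np.random.default_rng(config.seed)

    hba_ids = [f"HBA{i + 1:02d}" for i in range(config.n_hba)]
    hbd_ids = [f"HBD{i + 1:02d}" for i in range(config.n_hbd)]
    comp_ids = hba_ids + hbd_ids
    n_comp = len(comp_ids)

    n_const = round(config.frac_constant * config.n_descriptors)
    n_coll = round(config.frac_collinear * config.n_descriptors)
    n_clean = config.n_descriptors - n_const - n_coll
    names = [f"D{j + 1:03d}" for j in range(config.n_descriptors)]

    # clean descriptors first, then constant, then collinear copies of clean ones
    desc = np.empty((n_comp, config.n_descriptors))
    desc[:, :n_clean] = rng.normal(0.0, 1.0, size=(n_comp, n_clean))
    desc[:, n_clean : n_clean + n_const] = 1.0
    for j in range(n_coll):
        parent = j % n_clean
        desc[:, n_clean + n_const + j] = 2.0 * desc[:, parent] + 0.5
    table = ComponentDescriptorTable(pd.DataFrame(desc, index=comp_ids, columns=names))

    informative = names[: config.n_informative]
    if config.true_coefficients is not None:
        coefs = np.asarray(config.true_coefficients, dtype=float)
        if coefs.size != config.n_informative:
            raise ValueError("true_coefficients length must equal n_informative")
    else:
        lo, hi = config.coef_magnitude
        coefs = rng.uniform(lo, hi, size=config.n_informative) * rng.choice(
            [-1.0, 1.0], size=config.n_informative
        )

    # halide identity of each HBA: chloride / bromide / halide-free
    halide = rng.choice(["cl", "br", "none"], size=config.n_hba, p=[0.5, 0.3, 0.2])

    triples = [
        (a, d, r) for a in hba_ids for d in hbd_ids for r in config.ratios
    ]
    chosen = rng.choice(len(triples), size=config.n_mixtures, replace=False)

    records = []
    idx = 0
    desc_frame = table.frame
    for t_i in sorted(chosen):
        hba, hbd, (p, q) = triples[t_i]
        x1 = p / (p + q)
        x2 = q / (p + q)
        d1 = desc_frame.loc[hba, informative].to_numpy()
        d2 = desc_frame.loc[hbd, informative].to_numpy()
        pmix_vals = x1 * d1 + x2 * d2
        hal = halide[hba_ids.index(hba)]
        for T in config.temperatures:
            idx += 1
            mean = (
                config.intercept
                + float(coefs @ pmix_vals)
                + config.beta_temperature * T
            )
            sigma = mean + rng.normal(0.0, config.noise_sd)
            records.append(
                MixtureRecord(
                    record_id=f"R{idx:05d}",
                    comp1_id=hba,
                    comp2_id=hbd,
                    smiles1="C",  # placeholder SMILES; descriptors are synthetic
                    smiles2="O",
                    x1=x1,
                    x2=x2,
                    temperature=T,
                    cl_flag=int(hal == "cl"),
                    br_flag=int(hal == "br"),
                    sigma=max(sigma, 1e-3),  # responses are positive by construction
                )
            )
    dataset = MixtureDataset(records=records, provenance=f"synthetic(seed={config.seed})")

    truth = LinearModel(
        feature_names=tuple(f"{d}_pmix" for d in informative) + ("temperature",),
        coef=np.append(coefs, config.beta_temperature),
        intercept=config.intercept,
        coef_se=np.zeros(config.n_informative + 1),
        intercept_se=0.0,
        r2=float("nan"),
        r2_adj=float("nan"),
        f_stat=float("nan"),
        n_train=len(records),
        rho=float("nan"),
        residual_sd=config.noise_sd,
        metadata={"ground_truth": True, "seed": config.seed},
    )
    return dataset, table, truth
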