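"""The shipped surface-tension model (M12) for binary deep eutectic solvents.

A six-variable linear model predicting the surface tension sigma (mN/m)
of a binary DES from five weighted-mixture descriptors and the
temperature:

    sigma = 89.611
            + 0.405  * P_VSA_MR_6_pmix
            - 5.034  * Eig02_EA(dm)_pmix
            - 23.145 * CATS2D_02_AN_pmix
            + 8.835  * BLTF96_pmix
            - 25.191 * MATS5s_nmix
            - 0.104  * T            [K]

The descriptor inputs are Dragon-style 0D-2D descriptors combined by the
weighted-mixture formulas (see :mod:`mixqspr.features`): P_VSA-like on
molar refractivity at bin size 6; eigenvalue 2 of the dipole-weighted
edge adjacency matrix; CATS2D acceptor-negative at lag 2; Verhaar
fish baseline toxicity from MLOGP; and the Moran autocorrelation of lag 5
weighted by intrinsic state (the only ``nmix``-type term). Coefficients
are stored to exactly their published precision; the standard errors are
kept as metadata only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .linear import LinearModel

M12_FEATURES = (
    "P_VSA_MR_6_pmix",
    "Eig02_EA(dm)_pmix",
    "CATS2D_02_AN_pmix",
    "BLTF96_pmix",
    "MATS5s_nmix",
    "temperature",
)


@dataclass(frozen=True)
class M12Input:
    """One row of inputs for the frozen surface-tension model."""

    P_VSA_MR_6_pmix: float
    Eig02_EA_dm_pmix: float
    CATS2D_02_AN_pmix: float
    BLTF96_pmix: float
    MATS5s_nmix: float
    temperature: float

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"non-finite input {name}={v}")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (kelvin)")

    def as_row(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "P_VSA_MR_6_pmix": self.P_VSA_MR_6_pmix,
                    "Eig02_EA(dm)_pmix": self.Eig02_EA_dm_pmix,
                    "CATS2D_02_AN_pmix": self.CATS2D_02_AN_pmix,
                    "BLTF96_pmix": self.BLTF96_pmix,
                    "MATS5s_nmix": self.MATS5s_nmix,
                    "temperature": self.temperature,
                }
            ]
        )


def load_m12() -> LinearModel:
    """Deserialize the shipped M12 model from its packaged JSON."""
    text = resources.files("mixqspr").joinpath("data/m12.json").read_text()
    return LinearModel.from_json(text)


def predict_sigma_m12(inputs: M12Input) -> float:
    """Surface tension (mN/m) from one set of M12 inputs."""
    model = load_m12()
    return float(model.predict(inputs.as_row())[0])


def predict_sigma_m12_frame(frame: pd.DataFrame) -> pd.Series:
    """Vectorized M12 prediction over a DataFrame with the six input columns."""
    model = load_m12()
    return pd.Series(model.predict(frame), index=frame.index, name="sigma_pred_mN_per_m")
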