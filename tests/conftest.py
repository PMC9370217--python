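import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from mixqspr.data import MixtureDataset, MixtureRecord

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


def make_record(
    record_id="R1",
    comp1="ChCl",
    comp2="Gly",
    x1=1 / 3,
    temperature=298.15,
    sigma=55.0,
    cl_flag=1,
    br_flag=0,
):
    return MixtureRecord(
        record_id=record_id,
        comp1_id=comp1,
        comp2_id=comp2,
        smiles1="C[N+](C)(C)CCO.[Cl-]",
        smiles2="OCC(O)CO",
        x1=x1,
        x2=1 - x1,
        temperature=temperature,
        cl_flag=cl_flag,
        br_flag=br_flag,
        sigma=sigma,
    )


def make_dataset(spec):
    """Build a dataset from (comp1, comp2, x1, n_temperatures) tuples.

    Each mixture gets ``n_temperatures`` records at 298.15 + 10k K with a
    deterministic positive response.
    """
    records = []
    i = 0
    for comp1, comp2, x1, n_temp in spec:
        for k in range(n_temp):
            i += 1
            records.append(
                make_record(
                    record_id=f"R{i:03d}",
                    comp1=comp1,
                    comp2=comp2,
                    x1=x1,
                    temperature=298.15 + 10 * k,
                    sigma=40.0 + (i % 7),
                )
            )
    return MixtureDataset(records=records)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def random_regression(rng):
    """A well-conditioned random (X, y) pair as a named DataFrame."""

    def _make(n=30, p=3, noise=0.5, seed=None):
        g = np.random.default_rng(seed) if seed is not None else rng
        X = pd.DataFrame(
            g.normal(size=(n, p)), columns=[f"f{j + 1}" for j in range(p)]
        )
        beta = g.uniform(-3, 3, size=p)
        y = 5.0 + X.to_numpy() @ beta + g.normal(0, noise, size=n)
        return X, y

    return _make
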