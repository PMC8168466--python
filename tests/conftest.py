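import numpy as np
import pandas as pd
import pytest

from com6ar import ExpressionMatrix, SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def small_matrix():
    """4 genes x 6 samples, 3 case / 3 control, no structure."""
    rng = np.random.default_rng(7)
    data = pd.DataFrame(rng.standard_normal((4, 6)),
                        index=["G1", "G2", "G3", "G4"],
                        columns=[f"S{i}" for i in range(1, 7)])
    groups = pd.Series(["case"] * 3 + ["control"] * 3, index=data.columns)
    return ExpressionMatrix(data, groups)


@pytest.fixture
def default_sim():
    return SimulationConfig(seed=42)


def make_matrix(values, genes=None, samples=None, groups=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"G{i}" for i in range(1, values.shape[0] + 1)]
    samples = samples or [f"S{i}" for i in range(1, values.shape[1] + 1)]
    g = pd.Series(groups, index=samples) if groups is not None else None
    return ExpressionMatrix(pd.DataFrame(values, index=genes,
                                         columns=samples), g)
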