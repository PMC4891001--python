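import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from reosig.io import ExpressionMatrix, SurvivalTable


@pytest.fixture
def tiny_expr() -> ExpressionMatrix:
    """3 genes x 4 samples, hand-set values."""
    df = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0],
         [4.0, 3.0, 2.0, 1.0],
         [2.5, 2.5, 2.5, 2.5]],
        index=["GA", "GB", "GC"], columns=["S1", "S2", "S3", "S4"])
    return ExpressionMatrix(df)


@pytest.fixture
def six_patient_survival() -> SurvivalTable:
    """Hand-built two-group survival data with events and censoring."""
    return SurvivalTable(pd.DataFrame({
        "time": [2.0, 4.0, 5.0, 3.0, 7.0, 9.0],
        "event": [1, 1, 0, 1, 1, 0],
    }, index=[f"P{i}" for i in range(1, 7)]))


@pytest.fixture
def six_patient_groups() -> pd.Series:
    return pd.Series(["g1", "g1", "g1", "g2", "g2", "g2"],
                     index=[f"P{i}" for i in range(1, 7)])


def random_monotone_map(rng: np.random.Generator):
    """A random strictly increasing map built from a positive step function."""
    knots = np.sort(rng.uniform(-20, 20, 12))
    slopes = rng.uniform(0.05, 3.0, 13)
    offset = rng.uniform(-5, 5)

    def f(v):
        v = np.asarray(v, dtype=float)
        out = np.full(v.shape, offset, dtype=float)
        prev = np.minimum(v, knots[0])
        out += slopes[0] * (prev - (-25.0))
        lower = knots[0]
        for i in range(1, len(knots)):
            seg = np.clip(v, lower, knots[i]) - lower
            out += slopes[i] * seg
            lower = knots[i]
        out += slopes[-1] * np.clip(v - lower, 0, None)
        return out

    return f
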