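import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from rifnet.data import ExpressionMatrix

settings.register_profile("suite", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_matrix(rng) -> ExpressionMatrix:
    """8 features x 12 samples (6 H, 6 L) of log-normal FPKM."""
    values = pd.DataFrame(
        np.exp2(rng.normal(3.0, 1.0, size=(8, 12))),
        index=[f"F{i}" for i in range(8)],
        columns=[f"H{i}" for i in range(6)] + [f"L{i}" for i in range(6)])
    groups = pd.Series(["H"] * 6 + ["L"] * 6, index=values.columns)
    return ExpressionMatrix(values, groups)


def make_matrix(values: np.ndarray, n_h: int, n_l: int,
                feature_ids=None) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    if feature_ids is None:
        feature_ids = [f"F{i}" for i in range(values.shape[0])]
    cols = [f"H{i}" for i in range(n_h)] + [f"L{i}" for i in range(n_l)]
    df = pd.DataFrame(values, index=feature_ids, columns=cols)
    return ExpressionMatrix(df, pd.Series(["H"] * n_h + ["L"] * n_l,
                                          index=cols))
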