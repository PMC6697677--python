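import numpy as np
import pandas as pd
import pytest

from cerna_scope import ExpressionMatrix


def make_matrix(values, layer="mRNA", time_label="7M", n_case=None, feature_ids=None):
    """Build an ExpressionMatrix from an array; first half of columns = case."""
    values = np.asarray(values, dtype=float)
    n_feat, n_samp = values.shape
    if n_case is None:
        n_case = n_samp // 2
    if feature_ids is None:
        feature_ids = [f"f{i}" for i in range(n_feat)]
    sample_ids = [f"case_{i}" for i in range(n_case)] + [
        f"ctrl_{i}" for i in range(n_samp - n_case)
    ]
    groups = pd.Series(["case"] * n_case + ["control"] * (n_samp - n_case), index=sample_ids)
    frame = pd.DataFrame(values, index=feature_ids, columns=sample_ids)
    return ExpressionMatrix(layer, time_label, frame, groups)


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def matrix_factory():
    return make_matrix
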