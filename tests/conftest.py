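import numpy as np
import pandas as pd
import pytest

from mirpin.io import ExpressionMatrix, GroupLabels


def make_matrix(values, feature_ids=None, n_normal=None, scale_hint="log2"):
    """Build an ExpressionMatrix + GroupLabels from a 2-D array.

    Columns are split into normal (first ``n_normal``, default half) and
    tumor samples.
    """
    arr = np.asarray(values, dtype=float)
    n_feat, n_samp = arr.shape
    if n_normal is None:
        n_normal = n_samp // 2
    features = feature_ids or [f"f{i}" for i in range(n_feat)]
    samples = [f"n{i}" for i in range(n_normal)] + [f"t{i}" for i in range(n_samp - n_normal)]
    matrix = ExpressionMatrix(pd.DataFrame(arr, index=features, columns=samples),
                              scale_hint=scale_hint)
    labels = GroupLabels({s: ("normal" if s.startswith("n") else "tumor") for s in samples})
    return matrix, labels


@pytest.fixture
def toy_matrix():
    """One feature: normal [1, 2], tumor [4, 5] in log2 units."""
    return make_matrix([[1.0, 2.0, 4.0, 5.0]])


@pytest.fixture
def rng():
    return np.random.default_rng(20130530)
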