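import numpy as np
import pandas as pd
import pytest

from mirsig.datasets import ExpressionDataset


@pytest.fixture
def make_dataset():
    """Factory for small expression datasets from a raw matrix."""

    def _make(matrix, n_normal, n_tumor, feature_ids=None, dataset_id="toy"):
        matrix = np.asarray(matrix, dtype=float)
        n_feat = matrix.shape[0]
        feature_ids = feature_ids or [f"f{i:03d}" for i in range(n_feat)]
        samples = [f"N{i}" for i in range(n_normal)] + [f"T{i}" for i in range(n_tumor)]
        groups = pd.Series(["normal"] * n_normal + ["tumor"] * n_tumor, index=samples)
        values = pd.DataFrame(matrix, index=feature_ids, columns=samples)
        return ExpressionDataset(values=values, groups=groups, dataset_id=dataset_id)

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
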