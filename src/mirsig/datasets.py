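"""Expression-matrix container shared by every pipeline stage."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

NORMAL = "normal"
TUMOR = "tumor"
GROUPS = (NORMAL, TUMOR)


@dataclass
class ExpressionDataset:
    """A feature x sample expression matrix with group labels.

    Parameters
    ----------
    values
        DataFrame indexed by feature id with one column per sample id.
        Missing measurements are NaN.
    groups
        Series mapping every sample id to ``"normal"`` or ``"tumor"``.
    dataset_id
        Short identifier used in reports.
    """

    values: pd.DataFrame
    groups: pd.Series
    dataset_id: str = "dataset"

    def __post_init__(self) -> None:
        self.values = pd.DataFrame(self.values, dtype=float)
        self.groups = pd.Series(self.groups)
        if not self.values.index.is_unique:
            raise ValueError("duplicate feature ids")
        if not self.values.columns.is_unique:
            raise ValueError("duplicate sample ids")
        missing = set(self.values.columns) - set(self.groups.index)
        if missing:
            raise ValueError(f"samples without group label: {sorted(missing)}")
        self.groups = self.groups.loc[self.values.columns]
        bad = set(self.groups.unique()) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")

    # -- convenience accessors -------------------------------------------------

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def group_mask(self, group: str) -> np.ndarray:
        """Boolean mask over columns selecting one group."""
        if group not in GROUPS:
            raise ValueError(f"unknown group {group!r}")
        return (self.groups.values == group)

    def matrix(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def with_values(self, values: pd.DataFrame) -> "ExpressionDataset":
        """Return a copy of this dataset carrying a new value matrix."""
        return ExpressionDataset(values=values, groups=self.groups.copy(), dataset_id=self.dataset_id)

    def require_min_group_size(self, n: int = 2) -> None:
        for g in GROUPS:
            if int(self.group_mask(g).sum()) < n:
                raise ValueError(f"group {g!r} has fewer than {n} samples in {self.dataset_id}")
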