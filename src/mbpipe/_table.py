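"""In-memory containers shared by every pipeline stage.

The canonical orientation is samples x features, always.  On-disk
QIIME-classic tables are features-as-rows; :mod:`mbpipe.io` transposes on
read so that no downstream code ever has to guess.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Processing stages a table can be in, in pipeline order.
STAGES = ("raw", "grouped", "scaled", "standardized", "reduced")


@dataclass
class FeatureTable:
    """A samples x features numeric matrix with aligned IDs.

    Parameters
    ----------
    data
        DataFrame with sample IDs as the index and feature IDs as columns.
        Raw-stage values are read counts; later stages hold transformed
        values.
    stage
        One of :data:`STAGES`; tracks where in the pipeline the table is.
    """

    data: pd.DataFrame
    stage: str = "raw"

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample IDs: {dups}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature IDs: {dups}")
        if self.data.size == 0:
            raise ValueError("empty feature table")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("feature table contains non-numeric values")
        if not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                "non-finite value at sample "
                f"{self.data.index[bad[0]]!r}, feature {self.data.columns[bad[1]]!r}"
            )
        if self.stage == "raw" and (values < 0).any():
            raise ValueError("raw counts must be non-negative")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def with_data(self, data: pd.DataFrame, stage: str) -> "FeatureTable":
        """Return a new table at ``stage`` holding ``data``."""
        return FeatureTable(data=data, stage=stage)

    def copy(self) -> "FeatureTable":
        return replace(self, data=self.data.copy())


@dataclass
class LabelVector:
    """Binary classification target aligned to sample IDs.

    ``mapping`` records how the raw label values were coerced to {0, 1}
    (lexicographically smaller raw value becomes 0).
    """

    sample_ids: list[str]
    labels: np.ndarray
    mapping: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.sample_ids) != len(self.labels):
            raise ValueError("sample_ids and labels length mismatch")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample IDs in labels")
        present = set(np.unique(self.labels))
        if not present <= {0, 1}:
            raise ValueError(f"labels must be binary 0/1, got {sorted(present)}")
        if len(present) < 2:
            raise ValueError("single class: binary classification requires two classes")

    def __len__(self) -> int:
        return len(self.sample_ids)

    def to_series(self) -> pd.Series:
        return pd.Series(self.labels, index=self.sample_ids, name="label")
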