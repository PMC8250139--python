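"""Count scaling and constrained z-score standardization.

Two scalings are supported:

* log:       x -> log10(x + eps), eps > 0 guarding zeros (default 0.1);
* relative:  x -> x / (sample total), each sample row summing to 1.

After log scaling any of four standardizations may follow: none, z-score
per sample, z-score per feature, or per sample THEN per feature.  After
relative scaling only none or per-feature z-scoring are allowed — relative
rows carry the compositional constraint, and per-sample z-scoring it makes
no sense (each row already sums to a constant).

Z-scores use the population standard deviation (ddof=0); a constant vector
maps to all zeros rather than dividing by sigma=0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._table import FeatureTable

__all__ = [
    "ScalingSpec",
    "StandardizationSpec",
    "log_scale",
    "relative_scale",
    "apply_scaling",
    "zscore",
    "apply_standardization",
]

STANDARDIZATION_MODES = ("none", "zscore_sample", "zscore_feature", "zscore_both")
#: Modes legal under relative scaling.
RELATIVE_LEGAL_MODES = ("none", "zscore_feature")


@dataclass(frozen=True)
class ScalingSpec:
    method: str = "log"  # "log" | "relative"
    epsilon: float = 0.1

    def __post_init__(self) -> None:
        if self.method not in ("log", "relative"):
            raise ValueError(f"unknown scaling method {self.method!r}")
        if self.method == "log" and self.epsilon <= 0:
            raise ValueError("epsilon must be positive for log scaling")


@dataclass(frozen=True)
class StandardizationSpec:
    mode: str = "none"

    def __post_init__(self) -> None:
        if self.mode not in STANDARDIZATION_MODES:
            raise ValueError(
                f"unknown standardization mode {self.mode!r}; "
                f"expected one of {STANDARDIZATION_MODES}"
            )

    def check_against(self, scaling: ScalingSpec) -> None:
        if scaling.method == "relative" and self.mode not in RELATIVE_LEGAL_MODES:
            raise ValueError(
                f"standardization {self.mode!r} is not allowed with relative "
                f"scaling; allowed: {RELATIVE_LEGAL_MODES}"
            )


def log_scale(table: FeatureTable, epsilon: float = 0.1) -> FeatureTable:
    """Element-wise x -> log10(x + epsilon). Requires non-negative input."""
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    values = table.values
    if (values < 0).any():
        raise ValueError("log scaling requires non-negative values")
    out = pd.DataFrame(
        np.log10(values + epsilon), index=table.data.index, columns=table.data.columns
    )
    return table.with_data(out, stage="scaled")


def relative_scale(table: FeatureTable) -> FeatureTable:
    """Divide each value by its sample's total, so rows sum to 1."""
    values = table.values
    if (values < 0).any():
        raise ValueError("relative scaling requires non-negative values")
    totals = values.sum(axis=1)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        names = [table.sample_ids[i] for i in zero]
        raise ValueError(f"all-zero sample(s): {names}")
    out = pd.DataFrame(
        values / totals[:, None], index=table.data.index, columns=table.data.columns
    )
    return table.with_data(out, stage="scaled")


def apply_scaling(table: FeatureTable, spec: ScalingSpec) -> FeatureTable:
    if spec.method == "log":
        return log_scale(table, spec.epsilon)
    return relative_scale(table)


def zscore(table: FeatureTable, axis: str) -> FeatureTable:
    """Z-score per_sample (rows) or per_feature (columns), ddof=0.

    Constant vectors map to zeros (sigma guard).
    """
    if axis not in ("per_sample", "per_feature"):
        raise ValueError(f"axis must be per_sample or per_feature, got {axis!r}")
    values = table.values
    ax = 1 if axis == "per_sample" else 0
    if values.shape[ax] < 2:
        raise ValueError(f"need at least 2 entries along {axis} to z-score")
    mu = values.mean(axis=ax, keepdims=True)
    sigma = values.std(axis=ax, ddof=0, keepdims=True)
    centered = values - mu
    z = np.where(sigma > 0, centered / np.where(sigma > 0, sigma, 1.0), 0.0)
    out = pd.DataFrame(z, index=table.data.index, columns=table.data.columns)
    return table.with_data(out, stage="standardized")


def apply_standardization(
    table: FeatureTable,
    spec: StandardizationSpec,
    scaling: ScalingSpec | None = None,
) -> FeatureTable:
    """Apply the chosen z-scoring; ``zscore_both`` is sample THEN feature."""
    if scaling is not None:
        spec.check_against(scaling)
    if spec.mode == "none":
        return table.with_data(table.data.copy(), stage="standardized")
    if spec.mode == "zscore_sample":
        return zscore(table, "per_sample")
    if spec.mode == "zscore_feature":
        return zscore(table, "per_feature")
    return zscore(zscore(table, "per_sample"), "per_feature")
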