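"""Optional final dimension reduction of the merged, standardized table.

PCA keeps the fewest components whose cumulative explained-variance ratio
reaches the cutoff (default 0.7, inclusive, at least one component); ICA
fits a FastICA decomposition with that same component count.  Data are
mean-centered, not re-standardized — variance weighting is the
standardization stage's job.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA, FastICA

from ._table import FeatureTable

logger = logging.getLogger(__name__)

__all__ = ["ReductionSpec", "reduce_table", "n_components_for_cutoff"]


@dataclass(frozen=True)
class ReductionSpec:
    method: str = "none"  # "none" | "pca" | "ica"
    variance_cutoff: float = 0.7
    seed: int = 0  # ica only

    def __post_init__(self) -> None:
        if self.method not in ("none", "pca", "ica"):
            raise ValueError(f"unknown reduction method {self.method!r}")
        if self.method != "none" and not (0 < self.variance_cutoff <= 1):
            raise ValueError("variance_cutoff must be in (0, 1]")


def n_components_for_cutoff(ratios: np.ndarray, cutoff: float) -> int:
    """Smallest k with cumulative ratio >= cutoff (inclusive), k >= 1."""
    cum = np.cumsum(np.asarray(ratios, dtype=float))
    k = int(np.searchsorted(cum, cutoff - 1e-12) + 1)
    return max(1, min(k, len(cum)))


def reduce_table(table: FeatureTable, spec: ReductionSpec) -> FeatureTable:
    """Apply the configured reduction; ``none`` passes through unchanged."""
    if spec.method == "none":
        return table
    if table.n_samples < 2:
        raise ValueError("dimension reduction needs at least 2 samples")

    values = table.values
    max_rank = min(table.n_samples - 1, table.n_features)
    pca = PCA(n_components=max_rank, svd_solver="full")
    scores = pca.fit_transform(values)
    ratios = pca.explained_variance_ratio_
    k = n_components_for_cutoff(ratios, spec.variance_cutoff)
    if k > max_rank:
        logger.warning("capping components at rank bound %d", max_rank)
        k = max_rank

    if spec.method == "pca":
        out = _sign_fix(scores[:, :k], pca.components_[:k])
        cols = [f"PC{j + 1}" for j in range(k)]
    else:
        ica = FastICA(
            n_components=k,
            random_state=spec.seed,
            whiten="unit-variance",
            max_iter=2000,
            tol=1e-4,
        )
        import warnings

        from sklearn.exceptions import ConvergenceWarning

        with warnings.catch_warnings():
            # non-convergence only affects how independent the components
            # are, not determinism (seeded); downgrade to a log message
            warnings.simplefilter("ignore", ConvergenceWarning)
            sources = ica.fit_transform(values)
        if ica.n_iter_ >= 2000:
            logger.debug("FastICA hit the iteration cap (k=%d)", k)
        # deterministic presentation: order by projection variance, then
        # flip each mixing column so its largest-|entry| is positive
        order = np.argsort(-sources.var(axis=0, ddof=0), kind="stable")
        sources = sources[:, order]
        mixing = ica.mixing_[:, order]
        sources = _sign_fix(sources, mixing.T)
        cols = [f"IC{j + 1}" for j in range(k)]
        out = sources

    df = pd.DataFrame(out, index=table.data.index, columns=cols)
    return table.with_data(df, stage="reduced")


def _sign_fix(scores: np.ndarray, loadings: np.ndarray) -> np.ndarray:
    """Flip components so each loading vector's largest-|entry| is positive."""
    scores = scores.copy()
    for j in range(scores.shape[1]):
        pivot = np.argmax(np.abs(loadings[j]))
        if loadings[j, pivot] < 0:
            scores[:, j] = -scores[:, j]
    return scores
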