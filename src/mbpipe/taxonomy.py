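"""Taxonomy parsing and taxonomy-level feature merging.

Features (OTUs/ASVs) carry Greengenes/SILVA-style lineage strings
(``k__Bacteria; p__Firmicutes; ...``).  Merging truncates every lineage to
a chosen rank depth — order (4), family (5) or genus (6) — partitions the
features by truncated lineage, and collapses each group to one or more
representative columns by sum, mean, or a per-group PCA ("sub-PCA"): keep
the fewest principal components explaining at least half the group's
variance, and use the sample projections on them as the group's columns.

Sub-PCA expects already log-scaled input (the pipeline orders scaling
before sub-PCA grouping so the per-group PCA sees an approximately normal
input distribution).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._table import FeatureTable

logger = logging.getLogger(__name__)

RANK_PREFIXES = ("k", "p", "c", "o", "f", "g", "s")
#: Rank depth of each nameable level. Order/family/genus are the grouping
#: levels exposed by the pipeline; species consistently underperforms and
#: is excluded from the configuration grid.
LEVELS = {"order": 4, "family": 5, "genus": 6}

_SILVA_RE = re.compile(r"^D_(\d)__", flags=0)


@dataclass(frozen=True)
class TaxonomyPath:
    """One feature's lineage: ordered (rank prefix, name) pairs, depth 1-7."""

    ranks: tuple[tuple[str, str], ...]

    @property
    def depth(self) -> int:
        return len(self.ranks)

    def name_at(self, depth: int) -> str:
        """Name at 1-based rank ``depth``; empty if unpopulated."""
        if depth <= len(self.ranks):
            return self.ranks[depth - 1][1]
        return ""

    def truncated_key(self, depth: int) -> str:
        """Canonical serialization of the first ``depth`` ranks.

        Unpopulated trailing ranks serialize as bare prefixes (``g__``),
        so features unresolved at ``depth`` share the key of their deepest
        resolved ancestor.
        """
        parts = []
        for i in range(depth):
            prefix = RANK_PREFIXES[i]
            name = self.name_at(i + 1)
            parts.append(f"{prefix}__{name}")
        return ";".join(parts)


def parse_taxonomy(raw: str) -> TaxonomyPath:
    """Parse a semicolon-delimited lineage string.

    Handles Greengenes ``k__`` prefixes, SILVA ``D_0__`` prefixes
    (normalized onto the k/p/c/o/f/g/s scheme) and bare names (prefixes
    imputed positionally). Empty tokens (``g__``) record empty names.
    Raises on empty input or out-of-order prefixes.
    """
    if raw is None or not str(raw).strip():
        raise ValueError("empty taxonomy string")
    tokens = [t.strip() for t in str(raw).split(";")]
    # a trailing ';' produces one empty trailing token; drop it
    while tokens and tokens[-1] == "" and len(tokens) > 1:
        tokens.pop()
    ranks: list[tuple[str, str]] = []
    for pos, token in enumerate(tokens):
        if pos >= len(RANK_PREFIXES):
            raise ValueError(f"too many ranks ({len(tokens)}) in {raw!r}")
        token = _SILVA_RE.sub(lambda m: RANK_PREFIXES[int(m.group(1))] + "__", token)
        expected = RANK_PREFIXES[pos]
        if "__" in token:
            prefix, name = token.split("__", 1)
            prefix = prefix.strip().lower()
            if prefix != expected:
                raise ValueError(
                    f"out-of-order rank prefix {prefix!r} at position {pos + 1} "
                    f"(expected {expected!r}) in {raw!r}"
                )
        else:
            name = token
        ranks.append((expected, name.strip()))
    return TaxonomyPath(ranks=tuple(ranks))


@dataclass
class TaxonGroupIndex:
    """Partition of feature IDs by truncated taxonomy at a given level."""

    level: str
    groups: dict[str, list[str]]
    unresolved: set[str] = field(default_factory=set)

    @property
    def depth(self) -> int:
        return LEVELS[self.level]

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def feature_ids(self) -> list[str]:
        return [f for members in self.groups.values() for f in members]


def build_group_index(
    taxa: dict[str, TaxonomyPath], level: str
) -> TaxonGroupIndex:
    """Partition features by lineage truncated to ``level``.

    Features with an empty name at ``level`` are grouped under their
    deepest resolved ancestor key (the truncated key with bare trailing
    prefixes) and flagged unresolved, rather than dropped: dropping would
    silently change per-sample totals.
    """
    if level not in LEVELS:
        raise ValueError(f"unknown level {level!r}; expected one of {sorted(LEVELS)}")
    depth = LEVELS[level]
    groups: dict[str, list[str]] = {}
    unresolved: set[str] = set()
    for feature_id, path in taxa.items():
        key = path.truncated_key(depth)
        groups.setdefault(key, []).append(feature_id)
        if not path.name_at(depth):
            unresolved.add(key)
    return TaxonGroupIndex(level=level, groups=groups, unresolved=unresolved)


def _check_index(table: FeatureTable, index: TaxonGroupIndex) -> None:
    missing = set(index.feature_ids()) - set(table.feature_ids)
    if missing:
        raise ValueError(f"group index references features absent from table: {sorted(missing)}")


def group_sum(table: FeatureTable, index: TaxonGroupIndex) -> FeatureTable:
    """Merge each taxon group by summing member columns per sample."""
    return _group_agg(table, index, "sum")


def group_mean(table: FeatureTable, index: TaxonGroupIndex) -> FeatureTable:
    """Merge each taxon group by averaging member columns per sample."""
    return _group_agg(table, index, "mean")


def _group_agg(table: FeatureTable, index: TaxonGroupIndex, how: str) -> FeatureTable:
    _check_index(table, index)
    cols = {}
    for key, members in index.groups.items():
        block = table.data[members]
        cols[key] = block.sum(axis=1) if how == "sum" else block.mean(axis=1)
    out = pd.DataFrame(cols, index=table.data.index)
    return table.with_data(out, stage="grouped")


def group_sub_pca(table: FeatureTable, index: TaxonGroupIndex) -> FeatureTable:
    """Merge each taxon group by per-group PCA (sub-PCA).

    For each group the member columns are mean-centered per feature and
    decomposed; the smallest number of principal components whose
    cumulative explained-variance ratio reaches at least 0.5 is kept
    (always at least one), and the sample projections on those components
    become the group's output columns, named ``<group_key>|PC<j>``.

    Singleton groups yield their centered original column. A group with
    zero total variance yields a single all-zero column (with a warning).
    No per-group variance re-scaling is applied: the global scaling step
    already shaped the distribution.
    """
    _check_index(table, index)
    pieces: dict[str, np.ndarray] = {}
    for key, members in index.groups.items():
        block = table.data[members].to_numpy(dtype=float)
        centered = block - block.mean(axis=0, keepdims=True)
        total_var = float((centered**2).sum())
        if total_var <= 1e-300:
            logger.warning("sub-PCA group %r has zero variance; emitting zeros", key)
            pieces[f"{key}|PC1"] = np.zeros(block.shape[0])
            continue
        projections, k = _pca_half_variance(centered)
        for j in range(k):
            pieces[f"{key}|PC{j + 1}"] = projections[:, j]
    out = pd.DataFrame(pieces, index=table.data.index)
    return table.with_data(out, stage="grouped")


def _pca_half_variance(centered: np.ndarray) -> tuple[np.ndarray, int]:
    """Project onto the fewest PCs with cumulative variance ratio >= 0.5.

    Components are computed by SVD of the centered matrix; each loading
    vector is sign-flipped so its largest-magnitude entry is positive,
    making the output deterministic across runs and BLAS builds.
    """
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    var = s**2
    ratios = var / var.sum()
    k = int(np.searchsorted(np.cumsum(ratios), 0.5 - 1e-12) + 1)
    k = min(k, len(s))
    # largest-|loading|-positive sign convention, applied to projections too
    for j in range(k):
        pivot = np.argmax(np.abs(vt[j]))
        if vt[j, pivot] < 0:
            vt[j] = -vt[j]
            u[:, j] = -u[:, j]
    projections = u[:, :k] * s[:k]
    return projections, k
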