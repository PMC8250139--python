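"""Pipeline configurations: the valid choice grid and stage orchestration.

A configuration is one complete choice of

* taxonomy level:      order | family | genus
* grouping method:     sum | mean | sub_pca
* scaling:             log (with epsilon) | relative
* standardization:     none | sample | feature | both
                       (relative scaling admits only none | feature)
* dimension reduction: none | pca | ica

giving a grid of 3 x 3 x (4 + 2) x 3 = 162 configurations.

Stage ordering: sum/mean merge raw counts first, then scale, standardize
and reduce.  Sub-PCA instead scales FIRST and merges the scaled table, so
the per-group PCA sees an approximately normal input distribution; the
remaining stages follow as usual.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

from ._table import FeatureTable
from .reduction import ReductionSpec, reduce_table
from .scaling import (
    RELATIVE_LEGAL_MODES,
    STANDARDIZATION_MODES,
    ScalingSpec,
    StandardizationSpec,
    apply_scaling,
    apply_standardization,
)
from .taxonomy import (
    LEVELS,
    TaxonomyPath,
    build_group_index,
    group_mean,
    group_sub_pca,
    group_sum,
    parse_taxonomy,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "enumerate_configs", "run_pipeline", "parse_config_key"]

GROUPINGS = ("sum", "mean", "sub_pca")
_STD_SHORT = {"none": "none", "zscore_sample": "sample",
              "zscore_feature": "feature", "zscore_both": "both"}
_STD_LONG = {v: k for k, v in _STD_SHORT.items()}


@dataclass(frozen=True)
class PipelineConfig:
    """One complete preprocessing choice."""

    level: str = "genus"
    grouping: str = "sub_pca"
    scaling: ScalingSpec = field(default_factory=ScalingSpec)
    standardization: StandardizationSpec = field(default_factory=StandardizationSpec)
    reduction: ReductionSpec = field(default_factory=ReductionSpec)

    def validate(self) -> None:
        if self.level not in LEVELS:
            raise ValueError(f"unknown taxonomy level {self.level!r}")
        if self.grouping not in GROUPINGS:
            raise ValueError(f"unknown grouping {self.grouping!r}")
        self.standardization.check_against(self.scaling)

    @property
    def key(self) -> str:
        """Flat serialization used as the join key in results tables."""
        return (
            f"level={self.level}|group={self.grouping}"
            f"|scale={self.scaling.method}"
            f"|std={_STD_SHORT[self.standardization.mode]}"
            f"|reduce={self.reduction.method}"
        )

    def choices(self) -> dict[str, str]:
        """The config's option per choice group (attribution encoding)."""
        return {
            "taxonomy_level": self.level,
            "grouping": self.grouping,
            "scaling": self.scaling.method,
            "standardization": _STD_SHORT[self.standardization.mode],
            "reduction": self.reduction.method,
        }


def parse_config_key(key: str, epsilon: float = 0.1, ica_seed: int = 0) -> PipelineConfig:
    """Inverse of :attr:`PipelineConfig.key` (also accepts partial keys
    for subset filtering — missing fields take defaults)."""
    fields = dict(part.split("=", 1) for part in key.split("|") if part)
    cfg = PipelineConfig(
        level=fields.get("level", "genus"),
        grouping=fields.get("group", "sub_pca"),
        scaling=ScalingSpec(method=fields.get("scale", "log"), epsilon=epsilon),
        standardization=StandardizationSpec(mode=_STD_LONG[fields.get("std", "none")]),
        reduction=ReductionSpec(method=fields.get("reduce", "none"), seed=ica_seed),
    )
    cfg.validate()
    return cfg


def enumerate_configs(epsilon: float = 0.1, ica_seed: int = 0) -> list[PipelineConfig]:
    """The full valid grid, in deterministic canonical order (162 configs)."""
    configs = []
    for level, grouping, scale_method in itertools.product(
        sorted(LEVELS, key=LEVELS.get), GROUPINGS, ("log", "relative")
    ):
        modes = STANDARDIZATION_MODES if scale_method == "log" else RELATIVE_LEGAL_MODES
        for mode, red in itertools.product(modes, ("none", "pca", "ica")):
            cfg = PipelineConfig(
                level=level,
                grouping=grouping,
                scaling=ScalingSpec(method=scale_method, epsilon=epsilon),
                standardization=StandardizationSpec(mode=mode),
                reduction=ReductionSpec(method=red, seed=ica_seed),
            )
            cfg.validate()
            configs.append(cfg)
    return configs


def run_pipeline(
    table: FeatureTable,
    taxonomy: dict[str, str] | dict[str, TaxonomyPath],
    config: PipelineConfig,
) -> tuple[FeatureTable, dict[str, tuple[int, int]]]:
    """Run one configuration end to end.

    Parameters
    ----------
    table
        Raw count table, samples x features.
    taxonomy
        feature ID -> taxonomy string (or pre-parsed path) covering every
        feature in the table.
    config
        The preprocessing choice to apply.

    Returns
    -------
    processed, provenance
        The final table and an ordered record of per-stage output shapes
        ``{stage_name: (n_samples, n_features)}``.
    """
    config.validate()
    taxa = {
        fid: (path if isinstance(path, TaxonomyPath) else parse_taxonomy(path))
        for fid, path in taxonomy.items()
    }
    missing = set(table.feature_ids) - set(taxa)
    if missing:
        raise ValueError(f"features without taxonomy: {sorted(missing)[:5]} ...")
    index = build_group_index({f: taxa[f] for f in table.feature_ids}, config.level)

    provenance: dict[str, tuple[int, int]] = {"input": table.data.shape}

    def _record(name: str, t: FeatureTable) -> FeatureTable:
        provenance[name] = t.data.shape
        logger.info("stage %s -> %d x %d", name, *t.data.shape)
        return t

    try:
        if config.grouping == "sub_pca":
            t = _record("scale", apply_scaling(table, config.scaling))
            t = _record("group", group_sub_pca(t, index))
        else:
            grouper = group_sum if config.grouping == "sum" else group_mean
            t = _record("group", grouper(table, index))
            t = _record("scale", apply_scaling(t, config.scaling))
        t = _record(
            "standardize",
            apply_standardization(t, config.standardization, config.scaling),
        )
        t = _record("reduce", reduce_table(t, config.reduction))
    except Exception as exc:
        stage = list(provenance)[-1]
        raise RuntimeError(f"pipeline failed after stage {stage!r}: {exc}") from exc
    return t, provenance
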