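"""Grid sweep: preprocess every configuration, score it, attribute AUC."""

from __future__ import annotations

import logging

import pandas as pd

from ._table import FeatureTable, LabelVector
from .attribution import AttributionModel, AttributionResults
from .evaluate import ClassifierSpec, EvaluationRecord, cross_validated_auc
from .pipeline import PipelineConfig, enumerate_configs, run_pipeline

logger = logging.getLogger(__name__)

__all__ = [
    "evaluate_grid",
    "records_frame",
    "fold_frame",
    "attribute",
    "paired_option_delta",
]

_KEY_FIELD = {
    "taxonomy_level": "level",
    "grouping": "group",
    "scaling": "scale",
    "standardization": "std",
    "reduction": "reduce",
}


def evaluate_grid(
    table: FeatureTable,
    taxonomy: dict[str, str],
    labels: LabelVector,
    classifier: ClassifierSpec,
    configs: list[PipelineConfig] | None = None,
    n_folds: int = 5,
    seed: int = 0,
) -> list[EvaluationRecord]:
    """Cross-validated AUC of ``classifier`` under every configuration.

    All configurations see identical stratified fold splits (splits depend
    only on the labels and ``seed``).
    """
    if configs is None:
        configs = enumerate_configs(ica_seed=seed)
    records = []
    for cfg in configs:
        processed, _ = run_pipeline(table, taxonomy, cfg)
        rec = cross_validated_auc(
            processed, labels, classifier, n_folds=n_folds, seed=seed,
            config_key=cfg.key,
        )
        records.append(rec)
        logger.debug("%s: AUC %.3f +/- %.3f", cfg.key, rec.mean_auc, rec.std_auc)
    return records


def records_frame(records: list[EvaluationRecord]) -> pd.DataFrame:
    """Summary table: one row per (config, classifier)."""
    return pd.DataFrame(
        {
            "config_key": [r.config_key for r in records],
            "classifier": [r.classifier for r in records],
            "mean_auc": [r.mean_auc for r in records],
            "std_auc": [r.std_auc for r in records],
            "n_folds": [r.n_folds for r in records],
        }
    )


def fold_frame(records: list[EvaluationRecord]) -> pd.DataFrame:
    """Tidy per-fold table: one row per (config, classifier, fold)."""
    rows = [
        {
            "config_key": r.config_key,
            "classifier": r.classifier,
            "fold": i,
            "auc": auc,
        }
        for r in records
        for i, auc in enumerate(r.fold_aucs)
    ]
    return pd.DataFrame(rows)


def attribute(records: list[EvaluationRecord]) -> AttributionResults:
    """Fit the one-hot attribution regression on config-mean AUCs."""
    return AttributionModel.from_records(records).fit()


def paired_option_delta(
    records: list[EvaluationRecord],
    group: str,
    option_a: str,
    option_b: str,
) -> float:
    """Mean AUC(option_a) - AUC(option_b) over matched configurations.

    Matched pairs differ only in the chosen option of choice group
    ``group`` (``taxonomy_level``/``grouping``/``scaling``/
    ``standardization``/``reduction``); configurations whose partner does
    not exist in ``records`` (e.g. a standardization illegal under
    relative scaling) are skipped.
    """
    field = _KEY_FIELD[group]
    by_key = {r.config_key: r.mean_auc for r in records}
    deltas = []
    for key, auc in by_key.items():
        parts = dict(p.split("=", 1) for p in key.split("|"))
        if parts[field] != option_a:
            continue
        partner = "|".join(
            f"{k}={option_b if k == field else v}" for k, v in parts.items()
        )
        if partner in by_key:
            deltas.append(auc - by_key[partner])
    if not deltas:
        raise ValueError(f"no matched pairs for {group}: {option_a} vs {option_b}")
    return float(pd.Series(deltas).mean())
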