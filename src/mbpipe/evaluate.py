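"""Cross-validated AUC scoring of (configuration, classifier) pairs.

Three classifier families are supported with fixed hyperparameters —
tuning them is explicitly not this package's job:

* ``linear_svm``      — linear-kernel SVC with box constraint C = 0.1;
* ``boosted_trees``   — XGBoost, n_estimators=100, gamma=0.5,
                        min_child_weight=3;
* ``feedforward_net`` — two hidden layers of 100 (ReLU, then Sigmoid),
                        Adam lr 0.005, binary cross-entropy, batch 16.

Scoring is stratified k-fold ROC AUC on continuous classifier scores.
Fold assignment depends only on (sample order, labels, seed), never on
the feature values, so every configuration is evaluated on identical
train/test divisions.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC
from xgboost import XGBClassifier

from ._mlp import FeedForwardNet
from ._table import FeatureTable, LabelVector

__all__ = ["ClassifierSpec", "EvaluationRecord", "cross_validated_auc", "fold_indices"]

CLASSIFIER_FAMILIES = ("linear_svm", "boosted_trees", "feedforward_net")


@dataclass(frozen=True)
class ClassifierSpec:
    family: str = "linear_svm"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in CLASSIFIER_FAMILIES:
            raise ValueError(
                f"unknown classifier {self.family!r}; expected one of "
                f"{CLASSIFIER_FAMILIES}"
            )

    def build(self):
        if self.family == "linear_svm":
            return SVC(kernel="linear", C=0.1, random_state=self.seed)
        if self.family == "boosted_trees":
            return XGBClassifier(
                n_estimators=100,
                gamma=0.5,
                min_child_weight=3,
                random_state=self.seed,
                n_jobs=1,
                eval_metric="logloss",
            )
        return FeedForwardNet(seed=self.seed)


@dataclass
class EvaluationRecord:
    """Per-fold and summary AUC for one configuration and classifier."""

    config_key: str
    classifier: str
    fold_aucs: list[float]
    n_folds: int
    mean_auc: float = field(init=False)
    std_auc: float = field(init=False)

    def __post_init__(self) -> None:
        aucs = np.asarray(self.fold_aucs, dtype=float)
        if ((aucs < 0) | (aucs > 1)).any():
            raise ValueError("fold AUCs must lie in [0, 1]")
        self.mean_auc = float(aucs.mean())
        self.std_auc = float(aucs.std(ddof=0))


def fold_indices(
    labels: LabelVector, n_folds: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified train/test splits; a function of (labels, seed) only."""
    y = labels.labels
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros((len(y), 1)), y))


def fold_membership_hash(splits) -> str:
    """Stable digest of fold membership, for split-identity assertions."""
    h = hashlib.sha256()
    for train, test in splits:
        h.update(np.asarray(train, dtype=np.int64).tobytes())
        h.update(np.asarray(test, dtype=np.int64).tobytes())
    return h.hexdigest()


def _scores(clf, X_test: np.ndarray) -> np.ndarray:
    if hasattr(clf, "decision_function"):
        return np.asarray(clf.decision_function(X_test), dtype=float)
    return np.asarray(clf.predict_proba(X_test)[:, 1], dtype=float)


def cross_validated_auc(
    table: FeatureTable,
    labels: LabelVector,
    clf: ClassifierSpec,
    n_folds: int = 5,
    seed: int = 0,
    config_key: str = "",
) -> EvaluationRecord:
    """Mean/std test-fold ROC AUC of ``clf`` on the processed table.

    AUC is computed from continuous scores (margins or probabilities),
    never hard labels.  Raises if a class is missing from some training
    fold.
    """
    if table.sample_ids != labels.sample_ids:
        raise ValueError("table and labels are not aligned; call io.align first")
    if table.n_samples < 2 * n_folds:
        raise ValueError(
            f"need at least {2 * n_folds} samples for {n_folds}-fold CV, "
            f"got {table.n_samples}"
        )
    X = table.values
    y = labels.labels
    aucs = []
    for train, test in fold_indices(labels, n_folds, seed):
        if len(np.unique(y[train])) < 2 or len(np.unique(y[test])) < 2:
            raise ValueError(
                "a class is absent from some fold; use fewer folds or more samples"
            )
        model = clf.build()
        model.fit(X[train], y[train])
        aucs.append(float(roc_auc_score(y[test], _scores(model, X[test]))))
    return EvaluationRecord(
        config_key=config_key,
        classifier=clf.family,
        fold_aucs=aucs,
        n_folds=n_folds,
    )
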