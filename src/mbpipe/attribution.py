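"""Attribution of AUC to individual preprocessing choices.

Per-configuration mean test AUC is regressed on a one-hot encoding of the
configuration,

    yhat = b0 + b_level . x_level + ... + b_reduction . x_reduction ,

one binary indicator per (choice group, option).  The one-hot design is
rank-deficient (each group's indicators sum to the all-ones column), so
the coefficients are not unique; the regression is solved by minimum-norm
least squares and made identifiable by subtracting each choice group's
coefficient mean from its members.  The group means are re-absorbed into
the intercept, so fitted values are unchanged by the centering, and the
centered coefficients — the per-choice AUC contributions — sum to zero
within every group.

On a perfectly balanced grid any particular least-squares solution yields
the same centered coefficients; the grid here is only approximately
balanced (relative scaling structurally excludes two standardization
modes), which the report notes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evaluate import EvaluationRecord
from .pipeline import PipelineConfig, parse_config_key

__all__ = [
    "ChoiceGroup",
    "default_choice_groups",
    "one_hot_encode",
    "AttributionModel",
    "AttributionResults",
    "marginal_mean_auc",
]


@dataclass(frozen=True)
class ChoiceGroup:
    """One preprocessing step and its interchangeable options."""

    name: str
    options: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.options) < 2:
            raise ValueError(f"choice group {self.name!r} needs >= 2 options")


def default_choice_groups() -> list[ChoiceGroup]:
    """The five choice groups of the full pipeline grid (15 options)."""
    return [
        ChoiceGroup("taxonomy_level", ("order", "family", "genus")),
        ChoiceGroup("grouping", ("sum", "mean", "sub_pca")),
        ChoiceGroup("scaling", ("log", "relative")),
        ChoiceGroup("standardization", ("none", "sample", "feature", "both")),
        ChoiceGroup("reduction", ("none", "pca", "ica")),
    ]


def one_hot_encode(
    configs: list[PipelineConfig], groups: list[ChoiceGroup] | None = None
) -> pd.DataFrame:
    """Binary design matrix: one column per (group, option), one row per
    config; each row carries exactly one 1 per group."""
    groups = groups or default_choice_groups()
    columns = pd.MultiIndex.from_tuples(
        [(g.name, opt) for g in groups for opt in g.options],
        names=["group", "option"],
    )
    rows = []
    index = []
    for cfg in configs:
        choices = cfg.choices()
        row = np.zeros(len(columns))
        for g in groups:
            opt = choices[g.name]
            if opt not in g.options:
                raise ValueError(
                    f"config option {opt!r} not among group {g.name!r} options"
                )
            row[columns.get_loc((g.name, opt))] = 1.0
        rows.append(row)
        index.append(cfg.key)
    return pd.DataFrame(rows, index=index, columns=columns)


class AttributionModel:
    """Linear attribution of per-configuration AUC to pipeline choices.

    Parameters
    ----------
    design
        One-hot design matrix from :func:`one_hot_encode` (rows indexed by
        config key, MultiIndex (group, option) columns).
    auc
        Per-configuration response, aligned with ``design`` rows.
    """

    def __init__(self, design: pd.DataFrame, auc: np.ndarray | pd.Series) -> None:
        auc = np.asarray(pd.Series(auc), dtype=float)
        if len(auc) != len(design):
            raise ValueError("design and auc length mismatch")
        groups = design.columns.get_level_values("group").unique()
        if len(design) < len(groups) + 1:
            raise ValueError(
                f"need more configurations ({len(design)}) than choice groups "
                f"+ 1 ({len(groups) + 1})"
            )
        self.design = design
        self.auc = auc

    @classmethod
    def from_records(
        cls, records: list[EvaluationRecord], groups: list[ChoiceGroup] | None = None
    ) -> "AttributionModel":
        """Build from evaluation records (config-mean AUC per record)."""
        configs = [parse_config_key(r.config_key) for r in records]
        design = one_hot_encode(configs, groups)
        auc = np.array([r.mean_auc for r in records], dtype=float)
        return cls(design, auc)

    def fit(self) -> "AttributionResults":
        X = np.column_stack([np.ones(len(self.design)), self.design.to_numpy()])
        beta, *_ = np.linalg.lstsq(X, self.auc, rcond=None)  # minimum-norm
        intercept = float(beta[0])
        coef = pd.Series(beta[1:], index=self.design.columns)

        # center within each group; absorb the group means into the intercept
        centered = coef.copy()
        for group, block in coef.groupby(level="group"):
            mean = float(block.mean())
            centered.loc[group] = (block - mean).to_numpy()
            intercept += mean

        fitted = X @ beta
        ss_res = float(((self.auc - fitted) ** 2).sum())
        ss_tot = float(((self.auc - self.auc.mean()) ** 2).sum())
        r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
        return AttributionResults(
            model=self,
            intercept=intercept,
            coefficients=centered,
            fitted=pd.Series(fitted, index=self.design.index, name="predicted_auc"),
            observed=pd.Series(self.auc, index=self.design.index, name="observed_auc"),
            r2_train=r2,
        )


@dataclass
class AttributionResults:
    """Fit results: centered per-choice contributions and diagnostics."""

    model: AttributionModel
    intercept: float
    coefficients: pd.Series  # MultiIndex (group, option), centered per group
    fitted: pd.Series
    observed: pd.Series
    r2_train: float

    def predict(self, config: PipelineConfig | str) -> float:
        """Intercept plus the config's centered contributions."""
        cfg = parse_config_key(config) if isinstance(config, str) else config
        total = self.intercept
        for group, option in cfg.choices().items():
            if (group, option) not in self.coefficients.index:
                raise KeyError(f"unknown option {option!r} in group {group!r}")
            total += float(self.coefficients[(group, option)])
        return total

    def to_frame(self) -> pd.DataFrame:
        """Long-format report: (group, option, centered_coefficient)."""
        df = self.coefficients.rename("centered_coefficient").reset_index()
        return df

    def summary(self) -> str:
        lines = [
            "Preprocessing-choice AUC attribution",
            "=" * 52,
            f"n configurations: {len(self.observed):>5d}",
            f"intercept (grand AUC): {self.intercept:>8.4f}",
            f"R2 (train): {self.r2_train:>8.4f}",
            "",
            f"{'group':<17}{'option':<10}{'contribution':>14}",
            "-" * 41,
        ]
        for (group, option), value in self.coefficients.items():
            lines.append(f"{group:<17}{option:<10}{value:>+14.4f}")
        lines.append("-" * 41)
        lines.append("contributions sum to zero within each group")
        return "\n".join(lines)

    def plot_observed_vs_predicted(self, ax=None):
        """Scatter of observed vs predicted AUC over the grid."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 5))
        ax.scatter(self.fitted, self.observed, s=12, alpha=0.7)
        lo = min(self.fitted.min(), self.observed.min())
        hi = max(self.fitted.max(), self.observed.max())
        ax.plot([lo, hi], [lo, hi], "k--", lw=1)
        ax.set_xlabel("predicted AUC")
        ax.set_ylabel("observed AUC")
        ax.set_title(f"attribution fit (R$^2$ = {self.r2_train:.3f})")
        return ax

    def plot_coefficients(self, ax=None):
        """Grouped bar chart of centered contributions per choice."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 4))
        labels = [f"{g}\n{o}" for g, o in self.coefficients.index]
        groups = self.coefficients.index.get_level_values("group")
        palette = {g: f"C{i}" for i, g in enumerate(groups.unique())}
        ax.bar(
            range(len(labels)),
            self.coefficients.to_numpy(),
            color=[palette[g] for g in groups],
        )
        ax.set_xticks(range(len(labels)))
        ax.set_xticklabels(labels, fontsize=7)
        ax.axhline(0, color="k", lw=0.8)
        ax.set_ylabel("AUC contribution")
        return ax


def marginal_mean_auc(
    records: list[EvaluationRecord], group: ChoiceGroup, option: str
) -> float:
    """Mean of config-mean AUC over all configs selecting ``option``.

    The marginal view of a choice's effect: average over all options in
    all other steps.
    """
    if option not in group.options:
        raise ValueError(f"option {option!r} not in group {group.name!r}")
    selected = [
        r.mean_auc
        for r in records
        if parse_config_key(r.config_key).choices()[group.name] == option
    ]
    if not selected:
        raise ValueError(f"no configurations select {option!r} in {group.name!r}")
    return float(np.mean(selected))
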