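"""Synthetic 16S count data with planted, genus-level class signal.

The generator emulates the statistical structure a microbiome
classification task presents to the pipeline: a hierarchical taxonomy
(orders > families > genera > leaf features), compositional counts from a
multinomial read-allocation at a fixed sequencing depth, log-normal
abundance variation, zero inflation, and a class effect planted
MULTIPLICATIVELY (on the log10 scale) on a subset of genera — the regime
in which log scaling and genus-level merging are expected to help.

It does not emulate real cohorts: no phylogenetic correlation structure,
no batch effects, no variable library sizes beyond multinomial noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._table import FeatureTable, LabelVector
from .io import write_feature_table, write_labels

__all__ = ["SyntheticSpec", "generate_taxonomy", "generate_counts", "write_dataset"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Study-design parameters of one synthetic dataset.

    Defaults describe a modest but realistic 16S cohort: 100 samples, 20
    genera carrying 2-5 ASVs each, 5000 reads per sample, ~10% excess
    zeros, and a one-decade (10x) abundance shift in 4 informative genera.
    """

    n_samples: int = 100
    n_genera: int = 20
    features_per_genus: tuple[int, int] = (2, 5)
    n_informative_genera: int = 4
    effect_size: float = 1.0  # log10 fold change between classes
    dispersion: float = 0.5  # sd of per-entry log10 abundance noise
    zero_inflation: float = 0.1
    sequencing_depth: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative_genera > self.n_genera:
            raise ValueError("n_informative_genera must be <= n_genera")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if not (0 <= self.zero_inflation < 1):
            raise ValueError("zero_inflation must be in [0, 1)")
        lo, hi = self.features_per_genus
        if lo < 1 or hi < lo:
            raise ValueError("features_per_genus must be a (lo, hi) range, lo >= 1")


def _tree_shape(n_genera: int) -> tuple[int, int]:
    """Family and order counts giving >=2 orders and >=2 families per
    order whenever the genus count permits."""
    n_families = max(2, -(-n_genera // 2)) if n_genera >= 2 else 1
    n_families = min(n_families, n_genera) if n_genera >= 2 else 1
    n_orders = max(2, n_families // 2) if n_families >= 4 else min(2, n_families)
    return n_families, n_orders


def generate_taxonomy(spec: SyntheticSpec) -> dict[str, str]:
    """Greengenes-style 7-rank lineages for ``spec``'s features.

    Genera are nested in families, families in orders; each genus owns a
    seeded draw from ``features_per_genus`` leaf features. Deterministic
    under the spec seed.
    """
    rng = np.random.default_rng(spec.seed)
    n_families, n_orders = _tree_shape(spec.n_genera)
    lo, hi = spec.features_per_genus
    taxonomy: dict[str, str] = {}
    feature_no = 0
    for g in range(spec.n_genera):
        fam = g % n_families
        order = fam % n_orders
        lineage = (
            "k__Bacteria; p__SynthPhylum; c__SynthClass; "
            f"o__Order{order + 1:02d}; f__Family{fam + 1:02d}; "
            f"g__Genus{g + 1:02d}; s__"
        )
        for _ in range(int(rng.integers(lo, hi + 1))):
            feature_no += 1
            taxonomy[f"ASV_{feature_no:04d}"] = lineage
    return taxonomy


def generate_counts(
    spec: SyntheticSpec, taxonomy: dict[str, str]
) -> tuple[FeatureTable, LabelVector]:
    """Draw a count table and labels with the planted genus-level effect.

    Per sample: label ~ Bernoulli(0.5); per feature, latent log10
    abundance = genus baseline + feature offset + class effect (added for
    informative genera in class 1) + Normal(0, dispersion); counts are a
    multinomial draw of ``sequencing_depth`` reads with probabilities
    proportional to 10**latent, after zeroing a ``zero_inflation``
    fraction of entries (the draw renormalizes). A sample drawn all-zero
    is redrawn up to 10 times.
    """
    rng = np.random.default_rng(spec.seed)
    feature_ids = list(taxonomy)
    genus_of = np.array(
        [t.split("g__")[1].split(";")[0].strip() for t in taxonomy.values()]
    )
    genera = sorted(set(genus_of))
    if len(genera) < spec.n_informative_genera:
        raise ValueError("fewer distinct genera than n_informative_genera")
    informative = set(rng.choice(genera, size=spec.n_informative_genera, replace=False))
    is_informative = np.array([g in informative for g in genus_of])

    genus_baseline = dict(zip(genera, rng.normal(0.0, 1.0, size=len(genera))))
    base = np.array([genus_baseline[g] for g in genus_of])
    base = base + rng.normal(0.0, 0.5, size=len(feature_ids))  # feature offset

    labels = rng.integers(0, 2, size=spec.n_samples)
    if len(np.unique(labels)) < 2:  # tiny-n guard: force both classes
        labels[0] = 1 - labels[0]

    counts = np.zeros((spec.n_samples, len(feature_ids)), dtype=np.int64)
    for i in range(spec.n_samples):
        for _attempt in range(10):
            latent = base + rng.normal(0.0, spec.dispersion, size=len(feature_ids))
            if labels[i] == 1:
                latent = latent + spec.effect_size * is_informative
            weights = 10.0**latent
            if spec.zero_inflation > 0:
                keep = rng.random(len(feature_ids)) >= spec.zero_inflation
                weights = weights * keep
            total = weights.sum()
            if total <= 0:
                continue
            row = rng.multinomial(spec.sequencing_depth, weights / total)
            if row.sum() > 0:
                counts[i] = row
                break
        else:
            raise RuntimeError(f"could not draw a non-zero sample (row {i})")

    sample_ids = [f"S{i + 1:03d}" for i in range(spec.n_samples)]
    table = FeatureTable(
        pd.DataFrame(counts, index=sample_ids, columns=feature_ids), stage="raw"
    )
    # ground truth for tests/diagnostics: which genera carry the effect
    table.informative_genera = sorted(informative)
    y = LabelVector(
        sample_ids=sample_ids, labels=labels, mapping={"control": 0, "case": 1}
    )
    return table, y


def write_dataset(
    spec: SyntheticSpec, out_dir: str | Path
) -> dict[str, Path]:
    """Generate and write table (with embedded taxonomy), taxonomy file
    and labels in the exact on-disk formats :mod:`mbpipe.io` reads."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    taxonomy = generate_taxonomy(spec)
    table, labels = generate_counts(spec, taxonomy)
    paths = {
        "table": out_dir / "feature_table.tsv",
        "taxonomy": out_dir / "taxonomy.tsv",
        "labels": out_dir / "labels.csv",
    }
    write_feature_table(table, paths["table"], taxonomy=taxonomy)
    pd.DataFrame(
        {"feature_id": list(taxonomy), "taxonomy": list(taxonomy.values())}
    ).to_csv(paths["taxonomy"], sep="\t", index=False)
    write_labels(labels, paths["labels"])
    return paths
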