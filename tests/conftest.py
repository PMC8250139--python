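import numpy as np
import pandas as pd
import pytest

from mbpipe import FeatureTable, LabelVector, SyntheticSpec, generate_counts, generate_taxonomy

#: six features across three genera / two families / two orders
TOY_TAXONOMY = {
    "f1": "k__Bacteria; p__Firmicutes; c__Bacilli; o__Lactobacillales; "
          "f__Lactobacillaceae; g__Lactobacillus; s__",
    "f2": "k__Bacteria; p__Firmicutes; c__Bacilli; o__Lactobacillales; "
          "f__Lactobacillaceae; g__Lactobacillus; s__",
    "f3": "k__Bacteria; p__Firmicutes; c__Bacilli; o__Lactobacillales; "
          "f__Streptococcaceae; g__Streptococcus; s__",
    "f4": "k__Bacteria; p__Actinobacteria; c__Actinobacteria; o__Bifidobacteriales; "
          "f__Bifidobacteriaceae; g__Bifidobacterium; s__",
    "f5": "k__Bacteria; p__Actinobacteria; c__Actinobacteria; o__Bifidobacteriales; "
          "f__Bifidobacteriaceae; g__Bifidobacterium; s__",
    "f6": "k__Bacteria; p__Actinobacteria; c__Actinobacteria; o__Bifidobacteriales; "
          "f__Bifidobacteriaceae; g__Bifidobacterium; s__",
}


@pytest.fixture
def toy_table() -> FeatureTable:
    rng = np.random.default_rng(42)
    data = pd.DataFrame(
        rng.integers(0, 50, size=(4, 6)),
        index=[f"s{i}" for i in range(1, 5)],
        columns=list(TOY_TAXONOMY),
    )
    return FeatureTable(data, stage="raw")


@pytest.fixture
def toy_taxonomy() -> dict[str, str]:
    return dict(TOY_TAXONOMY)


@pytest.fixture
def toy_labels(toy_table) -> LabelVector:
    return LabelVector(sample_ids=toy_table.sample_ids, labels=np.array([0, 1, 0, 1]))


@pytest.fixture(scope="session")
def small_dataset():
    """A 40-sample synthetic cohort with a planted genus effect."""
    spec = SyntheticSpec(
        n_samples=40, n_genera=6, features_per_genus=(2, 4),
        n_informative_genera=2, effect_size=1.0, dispersion=0.4,
        zero_inflation=0.05, sequencing_depth=2000, seed=7,
    )
    taxonomy = generate_taxonomy(spec)
    table, labels = generate_counts(spec, taxonomy)
    return table, taxonomy, labels
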