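# mbpipe

Preprocessing of 16S rRNA OTU/ASV count tables for machine-learning
classification, with a built-in harness that measures how much each
preprocessing choice contributes to classification accuracy.

## The problem

16S sequencing yields a sparse samples × features count table whose
columns (OTUs/ASVs) carry a taxonomic lineage
(`k__Bacteria; p__Firmicutes; …; g__Lactobacillus; s__`). Raw counts are
a poor input for classifiers: the table is high-dimensional relative to
the number of samples, counts are compositional (they only carry
relative information at a fixed sequencing depth), and their
distribution is heavily zero-inflated and skewed. How the table is
preprocessed — at which taxonomic rank features are merged, how counts
are scaled, whether they are z-scored, whether a final dimension
reduction is applied — changes the downstream test AUC by amounts that
matter in biomarker applications.

`mbpipe` is for researchers building microbiome-based classifiers who
want (a) a reproducible preprocessing pipeline and (b) a quantitative
answer to "which preprocessing choices matter, and by how much, on my
data".

## The pipeline

A configuration is one choice per step, giving a grid of
3 · 3 · (4 + 2) · 3 = 162 valid combinations:

1. **Taxonomy merging** at level ∈ {order, family, genus}, by
   - *sum* or *mean* of the member features, or
   - ***sub-PCA***: per taxon group, center the member columns, run a PCA
     on that group alone, and keep the fewest principal components whose
     cumulative explained-variance ratio reaches ½ (always ≥ 1); the
     sample projections become the group's columns.
2. **Scaling**: elementwise `x → log10(x + ε)` with ε = 0.1, or relative
   abundance `x_ij → x_ij / Σ_i x_ij` (each sample row sums to 1).
   For sub-PCA, scaling runs *before* merging so each group-level PCA
   sees an approximately normal input.
3. **Standardization**: none, z-score per sample, z-score per feature,
   or both (sample then feature). Under relative scaling only
   none / per-feature are meaningful (rows are already constrained).
4. **Dimension reduction**: none, PCA at a 0.7 cumulative-variance
   cutoff, or ICA with the same component count.

Each configuration × classifier (linear SVM with C = 0.1, gradient
boosted trees, or a 100–100 ReLU/Sigmoid feedforward net — fixed
hyperparameters, never tuned) is scored by stratified k-fold
cross-validated ROC AUC on identical fold splits. The per-configuration
mean AUC is then regressed on a one-hot encoding of the configuration,

    ŷ = β₀ + β_level·x_level + β_grouping·x_grouping + … + β_reduction·x_reduction ,

and, because the one-hot design is rank-deficient, the coefficients are
made identifiable by centering each choice group's coefficients to zero
mean. The centered β's are the per-choice AUC contributions.

## Worked example

```python
import mbpipe as m

spec = m.SyntheticSpec(seed=1)          # 100 samples, 20 genera, depth 5000
taxonomy = m.generate_taxonomy(spec)
table, labels = m.generate_counts(spec, taxonomy)

config = m.parse_config_key("level=genus|group=sub_pca|scale=log|std=none|reduce=none")
processed, provenance = m.run_pipeline(table, taxonomy, config)
print("stages:", provenance)

record = m.cross_validated_auc(processed, labels, m.ClassifierSpec("linear_svm"),
                               n_folds=5, seed=1, config_key=config.key)
print(f"consensus config AUC: {record.mean_auc:.3f} +/- {record.std_auc:.3f}")

records = m.evaluate_grid(table, taxonomy, labels,
                          m.ClassifierSpec("linear_svm", seed=1), n_folds=5, seed=1)
print(f"log vs relative (paired): "
      f"{m.paired_option_delta(records, 'scaling', 'log', 'relative'):+.3f}")
print(m.attribute(records).summary())
```

prints

```
stages: {'input': (100, 70), 'scale': (100, 70), 'group': (100, 35), 'standardize': (100, 35), 'reduce': (100, 35)}
consensus config AUC: 0.952 +/- 0.025
log vs relative (paired): +0.073
Preprocessing-choice AUC attribution
====================================================
n configurations:   162
intercept (grand AUC):   0.9152
R2 (train):   0.6624

group            option      contribution
-----------------------------------------
taxonomy_level   order            -0.0039
taxonomy_level   family           -0.0146
taxonomy_level   genus            +0.0186
grouping         sum              +0.0138
grouping         mean             +0.0066
grouping         sub_pca          -0.0204
scaling          log              +0.0364
scaling          relative         -0.0364
standardization  none             -0.0141
standardization  sample           +0.0007
standardization  feature          +0.0162
standardization  both             -0.0028
reduction        none             +0.0038
reduction        pca              -0.0022
reduction        ica              -0.0016
-----------------------------------------
contributions sum to zero within each group
```

Reading it: the 70 generated ASVs merge into 35 sub-PCA columns at genus
level; the consensus configuration classifies the planted signal at AUC
0.95; and across the full 162-configuration grid, log scaling is worth
about +0.036 AUC over relative scaling (equivalently, +0.073 in the
directly paired comparison), genus-level merging beats coarser levels,
and z-scoring and dimension reduction matter little — on this synthetic
cohort, where the planted effect is a multiplicative genus-level shift.

The same workflow is available from the shell:

```bash
mbpipe simulate --n-samples 100 --seed 1 -o data/
mbpipe preprocess --table data/feature_table.tsv --labels data/labels.csv \
       --level genus --group sub-pca --scale log --std none --reduce none -o run/
mbpipe sweep --table data/feature_table.tsv --labels data/labels.csv \
       --classifier linear_svm -o sweep/
```

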