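# Methods

## Pipeline model

`mbpipe` treats 16S preprocessing as a four-stage transformation of a
samples × features count matrix `X` (entries `x_ij`, sample `i`,
feature `j` — an OTU/ASV with a Greengenes/SILVA lineage):

1. taxonomy merging (order / family / genus; sum, mean, or sub-PCA),
2. scaling (log10 with pseudocount, or per-sample relative abundance),
3. z-score standardization (none / per sample / per feature / both),
4. optional dimension reduction (PCA or ICA).

Stage order is merge → scale → standardize → reduce, with one
exception: sub-PCA merging runs *after* scaling, so that each per-group
PCA operates on an approximately normal input rather than raw skewed
counts. A consequence worth knowing: under sum/mean merging with
relative scaling, output rows sum to exactly 1 (scaling happens after
merging); under sub-PCA they do not.

### Sub-PCA merging

For each taxon group at the chosen level, the member columns are
centered per feature (no per-group variance rescaling — distribution
shape is the global scaling step's job) and decomposed by SVD. The
smallest k with cumulative explained-variance ratio ≥ 0.5 is kept,
inclusive of ties at exactly 0.5, and always k ≥ 1. Output columns are
the sample projections, named `<group_key>|PC<j>`. A singleton group
yields its centered column unchanged; a zero-variance group yields a
single all-zero column and a warning. Determinism: every loading vector
is sign-flipped so its largest-magnitude entry is positive, which makes
the output bit-stable across runs and BLAS builds.

### Taxonomy handling

Lineages are parsed from semicolon-delimited strings; Greengenes
(`k__`) and SILVA (`D_0__`) prefixes are normalized onto the
k/p/c/o/f/g/s scheme, bare names are imputed positionally, and
out-of-order prefixes are rejected. Levels map order = 4, family = 5,
genus = 6; species-level merging is not offered (it consistently
degrades accuracy relative to genus). Features with an empty name at
the chosen level are **not dropped** — dropping would silently change
per-sample totals. They are grouped under their deepest resolved
ancestor's truncated key (e.g. `…;f__Ruminococcaceae;g__`) and flagged
unresolved.

### Scaling and standardization

* log: `x → log10(x + ε)`, ε = 0.1 by default (configurable, > 0). The
  pseudocount guards zeros; with ε = 0.1, counts 0 / 0.9 / 99.9 map to
  −1 / 0 / 2.
* relative: `x_ij → x_ij / Σ_j x_ij` — each value divided by its
  *sample's* total, rows summing to 1. This is the standard per-sample
  relative abundance; an all-zero sample is an error, not a NaN.
* z-scores use the population standard deviation (ddof = 0); this makes
  z-scoring idempotent and lets constant vectors map cleanly to zeros
  (σ-guard) instead of dividing by zero. "Both" means per-sample then
  per-feature, in that order — column moments end at (0, 1), row
  moments generally do not.
* Under relative scaling only none / per-feature standardization are
  accepted: per-sample z-scoring a compositionally constrained row is
  degenerate. This constraint shapes the configuration grid
  (3 · 3 · (4 + 2) · 3 = 162) and is enforced at validation time.

### Dimension reduction

PCA keeps the fewest components with cumulative explained-variance
ratio ≥ cutoff (default 0.7, inclusive, k ≥ 1, capped at
min(n_samples − 1, n_features)); input is mean-centered but not
re-standardized, since the standardization stage already decided the
variance weighting. ICA (FastICA, seeded) uses the component count k
the PCA rule produces; its components are presented deterministically
by sorting on projection variance and applying the
largest-loading-positive sign convention. FastICA occasionally stops at
the iteration cap (2000); this affects only how independent the
components are, never reproducibility.

## Evaluation

Each configuration × classifier is scored by stratified k-fold
cross-validated ROC AUC on continuous scores (margins/probabilities,
never hard labels). Fold assignment depends only on (sample order,
labels, seed) — never on features — so all 162 configurations are
compared on identical train/test divisions. The default is 5 folds;
10-fold is available by flag. Classifier hyperparameters are fixed
(linear SVM C = 0.1; XGBoost n_estimators = 100, γ = 0.5,
min_child_weight = 3; feedforward net 100–100 with ReLU then Sigmoid,
Adam at 0.005, binary cross-entropy, batch 16) — the object of study is
the preprocessing, not the learner. The net trains a fixed 100 epochs
with no early stopping so runs are deterministic and comparable; it is
implemented directly in numpy because its per-layer activation pattern
(ReLU, then Sigmoid, then a sigmoid output) is not expressible in
sklearn's MLP.

## Attribution regression

Per-configuration mean AUC is regressed on a one-hot encoding with one
binary column per (choice group, option) — 15 columns over 5 groups —
plus an intercept. Each group's indicators sum to the all-ones column,
so the design is rank-deficient and coefficients are not unique; the
system is solved by minimum-norm least squares, and identifiability is
restored by subtracting each group's coefficient mean from its members
(the means are re-absorbed into the intercept, leaving fitted values
unchanged). The null space of the design is exactly the per-group
constant shifts, so the centered coefficients are invariant to which
particular least-squares solution is found — this holds even though the
grid is only *approximately* balanced (per-sample and both z-scoring
occur only under log scaling). That same imbalance means raw marginal
mean AUCs for the standardization options absorb part of the scaling
effect, while the regression's centered coefficients do not; the two
views agree on balanced groups. Attribution uses config-mean AUCs (not
fold-level values) and is fitted separately per classifier family.

## Synthetic data generator

The generator defines the study conditions under which the package's
guarantees are demonstrated. Defaults: 100 samples, 20 genera nested in
families and orders (≥ 2 orders, ≥ 2 families per order when counts
permit), 2–5 ASVs per genus, sequencing depth 5000, zero-inflation 0.1,
per-entry log10 noise 0.5, and a class effect of 1.0 (a one-decade
abundance shift) planted in 4 informative genera. Per sample, the label
is Bernoulli(0.5); each feature's latent log10 abundance is genus
baseline + feature offset + class effect + noise; reads are allocated
by a single multinomial draw per sample (capturing compositionality —
pushing informative genera up pushes everything else down), after
zeroing a random fraction of entries. Effects are planted
multiplicatively at genus level deliberately: that is the regime in
which log scaling and genus-level merging are expected to help, and the
generator's job is to make that mechanism available, not to guarantee
any particular AUC margin.

What the generator does not emulate: phylogenetically realistic tree
shapes, batch effects, variable library sizes, taxa correlated through
ecology rather than taxonomy. Passing tests therefore demonstrate that
the pipeline recovers a planted multiplicative genus-level signal and
that its stages satisfy their algebraic contracts — not that any
particular preprocessing wins on a given real cohort.

## Problem sizes and numerical choices

The test suite and the acceptance script run the full 162-configuration
grid with the linear SVM at the generator's default size
(100 samples × ~70 features, 5-fold CV); directional claims
(log > relative, genus ≥ order, paired over matched configurations) are
sign-tested over 10 generator seeds, the no-signal chance-level check
averages grid-mean AUC over 5 seeds (single datasets fluctuate by
±0.1 because configurations within one dataset are strongly
correlated), and noisy attribution recovery uses 20 seeds at noise
σ = 0.01. Oracle comparisons use 1e-8 tolerances (eigendecomposition vs
SVD), moment checks 1e-9, row-sum conservation 1e-12.

Tie-breaks and guards collected in one place: variance cutoffs are
inclusive (a 1e-12 slack absorbs cumulative-sum rounding at exact
ties); σ = 0 vectors z-score to zeros; empty taxonomy names serialize
as bare prefixes (`g__`) in group keys; duplicate IDs, missing counts,
all-zero samples, out-of-order rank prefixes and single-class labels
are hard errors rather than silent repairs.

## Known limitations

* Binary classification only; no multi-class AUC.
* The attribution model is additive — interactions between choices
  (e.g. sub-PCA × level) are absorbed into the residual; R² on real
  grids is accordingly well below 1.
* Sub-PCA column counts vary with the data (Σ k_group), so feature
  dimensionality is not comparable across configurations.
* BIOM ingestion is out of scope; convert to TSV/CSV upstream.
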