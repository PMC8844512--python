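# Methods

## The 188D descriptor

A validated sequence (uppercase, 20 canonical letters, length L ≥ 2) maps
to 188 numbers in [0, 1]:

* **AAC (features 1–20).** count(a)/L for each amino acid, alphabetical by
  one-letter code. Sums to 1.
* **CTD (features 21–188).** For each of 8 physicochemical properties, the
  20 amino acids are partitioned into 3 disjoint groups and a 21-feature
  block is emitted:
  * *Composition* (3): fraction of residues per group; sums to 1.
  * *Transition* (3): fraction of the L−1 adjacent pairs whose two residues
    fall in different groups, one entry per unordered group pair, taken in
    the cyclic order (g1,g2), (g2,g3), (g3,g1); block sum ≤ 1.
  * *Distribution* (15): for each group with n occupied positions, the
    1-based position of the m-th occurrence divided by L, for m = 1,
    ⌈0.25n⌉, ⌈0.5n⌉, ⌈0.75n⌉ (each floored at 1) and n. Values in (0, 1],
    non-decreasing across the five quantiles; an empty group contributes
    five zeros.

Design choices where the convention is genuinely open, all unit-tested:

* **Property tables.** The classical Dubchak-style 3-group partitions
  (as distributed with descriptor toolkits such as iFeature/propy) for
  hydrophobicity, normalized van der Waals volume, polarity,
  polarizability, charge, secondary structure and solvent accessibility,
  plus the surface-tension grouping GQDNAHR / KTSEC / ILMFPWYV. Partitions
  are overridable from a plain-text TSV (`load_partitions`); any override
  must still disjointly cover the 20 amino acids. Group labels name
  property bins; full numeric identity with other 188D implementations is
  not guaranteed beyond the structure, since block orderings vary across
  codebases.
* **Index contract.** Hydrophobicity groups are ordered (hydrophobic,
  polar, neutral) and transition pairs cyclically, so 1-based feature 21 is
  the hydrophobic composition and feature 26 the neutral↔hydrophobic
  transition — the two indices canonically reported as the strongest
  aquaporin discriminators. The same cyclic convention applies to all
  eight properties.
* **Scale.** D descriptors are fractions, not percentages, so all 188
  features share the [0, 1] scale; ANOVA is scale-invariant per feature,
  and classifiers see homogeneous inputs.
* **Quantile convention.** ⌈q·n⌉ floored at 1; "first"/"last" are exact.
  The minimum sequence length 2 is the smallest input for which every
  C/T/D descriptor is defined.

Validation rejects whole records containing non-canonical residues
(B, J, O, U, X, Z, gaps) rather than stripping characters: repair would
silently distort composition and transition frequencies. Exact-duplicate
removal keeps the first occurrence; similarity-based redundancy reduction
(e.g. CD-HIT clustering at 90% identity) is an upstream external step — the
pipeline accepts pre-clustered FASTA and the holdout splitter is therefore
not identity-aware (a documented caveat).

## Feature selection

`anova_f` computes, per feature, F = MSB/MSW with MSB = Σ n_g(x̄_g − x̄)²/(k−1)
and MSW = Σ_g Σ_i (x_gi − x̄_g)²/(N−k), k = 2; for two classes F equals the
squared pooled-variance t statistic (a test asserts this to 1e−10, plus
agreement with scikit-learn's `f_classif`). Degenerate cases are ordered
deterministically: zero within-class variance with non-zero between-class
variance → +∞ (a perfectly separating feature, ranked first); a constant
feature → 0. Ties break by ascending feature index.

IFS evaluates rank-ordered prefixes d from a grid (default: every size) by
mean cross-validated accuracy (MCC optional) and returns the smallest d
attaining the maximum. By construction the optimum is ≥ the full-feature
entry whenever the full size is in the grid.

PCA projection (for 2-D visualisation of selected features) uses a fixed
sign convention — the largest-magnitude loading of each component is made
positive — so plots reproduce across runs and library versions.

## Evaluation

Sn, Sp and Acc are percentages; MCC ∈ [−1, 1]; AUROC ∈ [0, 1] via the
rank/Mann–Whitney formulation with ties counted ½, which equals the
trapezoidal area under the ROC curve (asserted to 1e−12 against the curve
returned by `roc_curve`). Zero denominators (a class absent from truth or
prediction, or a zero MCC factor) evaluate to 0. Stratified k-fold CV
(default k = 10) reports both the unweighted mean over folds (default, the
convention behind most published tables) and pooled out-of-fold metrics,
since published numbers rarely state which was used; fold sizes are
near-equal so the difference is second-order. All seeds are explicit and
recorded, so every reported number is reproducible.

## Classifiers

Six families behind one train/predict interface, with documented defaults
(the usual published pipelines state none): random forest 500 trees; SVM
RBF with probability scores; gradient boosting via XGBoost (scikit-learn
fallback selectable with `hyperparameters={"backend": "sklearn"}`);
logistic regression with max_iter = 2000; Gaussian naive Bayes; CART
decision tree. Scores are positive-class probabilities; the decision
threshold is 0.5. No class reweighting by default — imbalance experiments
are meant to *show* the Sn/MCC degradation at ratios 1:2…1:all, not mask
it; a class-weight hyperparameter can be passed through. Models serialize
with a format version and the fit-time feature-name order, and prediction
refuses inputs whose columns differ (the CLI `predict` command projects a
full 188D encoding onto a selected-prefix model by name before applying
the strict check).

## Synthetic benchmark

The generator emulates the one property of the real problem that the
descriptor is supposed to exploit: positives have n_segments = 6
transmembrane-like hydrophobic segments (Poisson lengths, mean 20)
alternating with polar loops (Poisson, mean 25), total ≈ 295 residues;
negatives are i.i.d. draws from a background composition (uniform over the
20 amino acids by default). Inside segments the hydrophobic group
{C,L,V,I,M,F,W} is enriched by a factor (default 6) and renormalized, so
expected hydrophobic content is ≈ 0.76 in segments vs 0.35 in background,
≈ 0.52 overall for positives. The class signal is thus routed exclusively
through hydrophobicity, making feature-ranking recovery (top feature in
the hydrophobicity block; empirically feature 21 itself) a meaningful
check rather than a tautology. Default class sizes are 150 + 150, on the
order of the positive pool available to real curated aquaporin datasets.

Negative lengths follow the same architecture-derived distribution as the
positives by default. This is deliberate: the distribution descriptors
encode relative positions whose statistics depend on L (the first
occurrence of a group concentrates near 1/(p·L)), so mismatched length
laws would let a classifier separate the classes on length alone. With
matched lengths, setting `hydrophobic_enrichment = 1` makes the two
generators distributionally identical — an exchangeable null under which
the full pipeline's AUROC must sit at chance, the package's leakage guard.
An optional `neg_len_range=(lo, hi)` draws negative lengths uniformly
instead, reintroducing length as an explicit nuisance signal for
robustness experiments.

What the generator does **not** emulate: real aquaporin motifs (e.g. NPA),
evolutionary conservation and homology structure, realistic amino-acid
background frequencies, or inter-sequence redundancy. Passing the
synthetic checks therefore demonstrates that the encoder, ranking and CV
machinery are correct and leak-free — not that the trained model transfers
to real proteomes; real use requires curated positive/negative FASTA pools
(and upstream identity clustering).

## Problem sizes and numerics

Tests and the acceptance suite run at the generator defaults (300
sequences, 10-fold CV, 500-tree forests) or smaller; the encoder oracle
compares 188 entries on hundreds of short random sequences at 1e−12, the
AUROC implementation is checked exhaustively against pairwise brute force
for vectors up to length 8, and the chance-level AUROC target uses 1,000 +
1,000 labels with uniform scores (sampling tolerance ±0.03). All
randomness flows from explicit integer seeds (numpy `default_rng`,
scikit-learn `random_state`).

## Known limitations

* The 8 property tables are the field's conventional ones, not a uniquely
  defined standard; other 188D implementations may order blocks (or bin
  borderline residues) differently, so cross-implementation feature
  vectors agree structurally but not necessarily numerically.
* No similarity-aware splitting: with redundant input, CV estimates are
  optimistic. Cluster first.
* No probability calibration, confidence intervals, or DeLong-style AUROC
  comparisons; reported metrics are point estimates under the recorded
  seeds.
* SVM probabilities come from Platt scaling inside scikit-learn's SVC and
  inherit its internal 5-fold variability (seeded here).
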