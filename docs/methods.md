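# Methods

This note records the modeling assumptions, defaults and numerical choices
behind `solstack`, and what the synthetic benchmarks do and do not
demonstrate.

## Curation protocol

Records are grouped by RDKit canonical SMILES (default canonicalization
with aromatic perception; no tautomer or charge normalization — the
deeper normalization layers are deliberately avoided because they can merge
chemically distinct records). Unit conversion treats mg/mL and g/L as
numerically identical and divides by the molecular weight from average
atomic masses before taking log₁₀; Log S inputs pass through.

Filtering drops single-(heavy-)atom structures, species with net formal
charge, records outside 25 ± 2 °C (when a temperature is present; a missing
temperature is kept, since curated source tables are usually pre-filtered
to room temperature), and non-aqueous solvents. Salts written covalently,
inorganics and metal-containing molecules are kept on purpose: the model is
meant to cover them.

Merging per compound: values differing by less than 0.01 log units are
collapsed to a single occurrence first (greedy clusters over the sorted
list, anchored at each cluster's first element; each cluster is replaced by
its mean). One or two values are averaged unconditionally — with two
records there is no statistical basis for calling either an outlier. With
more, while the sample SD (ddof = 1) exceeds 0.5 log units and more than
two values remain, the value farthest from the current mean is removed;
ties break toward the value farther from the median, then toward the lower
value, making the procedure deterministic and permutation-invariant. The
0.5 threshold is the conventional estimate of interlaboratory error in
solubility determination; it is configurable (`CurationConfig.sd_threshold`).

Consequences worth knowing: a gross outlier in a *two*-record group is
averaged in, not removed (by design); and with zero measurement noise,
identical replicates collapse to one occurrence, so a single outlier then
faces the two-record rule. Both behaviors are inherited from the protocol's
stated rules, and the synthetic tests assert around them rather than hiding
them.

External free-text records (database annotations) are dropped when source,
temperature, solvent or unit is unspecified; bounded descriptions ("< 0.01
g/L") are kept as class-only records when the bound pins a unique class
(an upper bound can only pin the least-soluble class, a lower bound the
most-soluble one); anything spanning several classes is dropped as
ambiguous.

## Class mapping

Classes 0–6 are defined on the mL-of-water-per-gram scale with left-closed
intervals [1,10), [10,30), … — exactly 1 mL/g is class 1, i.e. a boundary
solubility falls to the more-soluble class on the g/L scale. The mapping is
total (S = 0 → class 6) and weakly monotone, which the tests assert by
property.

## Feature pipeline

All RDKit 2-D descriptors are computed per molecule; any descriptor that is
non-finite or raises for at least one molecule in the batch is dropped
globally with its name recorded (for metal-containing molecules this
removes exactly the 12 partial-charge/BCUT descriptors whose Gasteiger
charges are undefined). Zero-variance columns are removed before
correlation pruning (Pearson R is undefined on them). Pruning is a greedy
scan in the native descriptor order: a feature is dropped when its |R| with
any earlier-kept feature exceeds 0.9. The scan order is a convention —
removal sets are order-dependent — chosen for determinism. Standardization
is a z-score with population SD fitted on training rows only; a zero-SD
feature on held-out data is emitted as 0 (continuity). For classification,
features with seeded random-forest importance (500 trees, normalized to sum
to one) below 0.01 are discarded; regression keeps the full pruned set.

## Stacking

Base learners: random forest, XGBoost, LightGBM, RBF-kernel SVM, with
modest default hyperparameters (200–300 trees/rounds) exposed per spec.
The meta-learner is fitted on out-of-fold base predictions only (5-fold,
shuffled, seeded); bases are then refitted on the full training set for
inference — the canonical stacking protocol. Classification stacking uses
the concatenated per-class probability columns of every base as the meta
design, with logistic regression on top. The Ensemble-Mean is the
arithmetic mean of the Lasso-, Ridge- and MLR-meta stacking regressors; the
sample SD (ddof = 1) of the three member predictions is retained per
molecule as a self-agreement signal. All seeds derive from one root seed.

The `stacking_benchmark` helper scores base learners by out-of-fold RMSE on
a shared fold split and the stacking level by cross-validating the
meta-learner on the out-of-fold design, so neither level is ever scored on
a row it trained on.

Class re-balancing (random under/over-sampling, SMOTE, Borderline-1/2,
SMOTE+ENN) is implemented directly on nearest-neighbor queries: SMOTE
interpolates uniformly on segments between same-class neighbors (k = 5);
Borderline restricts seeds to points with at least half majority-class
neighbors among their m = 10 nearest; Borderline-2 draws half of the
synthetics toward majority neighbors with gaps in [0, 0.5]; ENN removes
points whose 3-NN majority vote disagrees with their label. Re-balancing is
for training folds only and never mutates its inputs.

## Metrics

Regression: RMSE, R², MAPD and %LogS ± 0.7 / ± 1.0. MAPD is computed on
the Log S scale, consistent with every other metric here, and is reported
missing when a reference value is exactly zero. The boundary |error| = δ
counts as within δ. Classification: accuracy plus macro-averaged
precision/recall/F1 and one-vs-rest macro AUC/AP over classes present in
the reference (absent classes are excluded with a warning); macro averaging
is the defensible choice under the strong class imbalance of solubility
data. Consistency between model views reports exact and within-one-class
agreement percentages.

## Applicability domain

*Euclidean*: score = distance to the training centroid of the standardized
descriptors (a k-NN mean-distance variant is available); threshold = the
empirical coverage-level quantile (default 0.95, linear interpolation
between order statistics) of the training scores; boundary equality counts
inside. *Density*: 2-D t-SNE embedding of the training set (fixed seed,
PCA initialization, perplexity 30 capped at (n−1)/3), Gaussian KDE with
Scott's-rule bandwidth, and the highest-density-region cutoff at the
(1 − coverage) quantile of training-point densities. Both constructions
give training self-coverage equal to the coverage level up to 1/n rounding.
Fitted thresholds are dataset- and seed-specific values stored on the
model, never constants.

t-SNE has no native out-of-sample transform. Queries are placed at the
inverse-distance-weighted average of the embedded coordinates of their
k = 10 nearest training neighbors in descriptor space. That placement is an
interpolation, and testing showed it silently maps far outliers *into* the
embedded cloud (their nearest neighbors form a local surface patch); a
query whose mean neighbor distance exceeds the maximum observed among
training molecules is therefore outside the domain by definition. The gate
does not affect training self-coverage. Joint re-embedding of train + query
is available behind a flag but is non-inductive (the training embedding
then depends on the query set) and is flagged as such.

The AD-shrink experiment restricts training data to the inside-AD subset at
each coverage level and reports 5-fold CV RMSE; on data whose outliers sit
far from the centroid with noisy labels, error does not grow as the domain
tightens, which the tests assert as a non-negative Spearman correlation
between coverage and RMSE.

## Reliability triage

The four trust criteria — inside the Euclidean AD, inside the density HDR,
regression-derived class within one class of the classifier's class, and
ensemble member SD ≤ 0.5 log units — are this package's reconstruction of
a workflow that is usually depicted rather than enumerated; they are the
four reliability signals the surrounding analysis actually produces. Each
is individually toggleable (a disabled criterion counts as met), the class
agreement can be switched to exact match, and the SD tolerance is
configurable. Groups: A = 4 criteria met, B = 3, C = 2, D ≤ 1. Tightening
any single criterion can only demote molecules, never promote them.

## Synthetic data

The generator emulates the statistical structure the pipeline must face:
molecule libraries from a small fragment grammar (charge-neutral chains,
rings, heteroatoms; an optional metal-cap flag exercises the
descriptor-drop path), molecular weights in 150–450 g/mol, ground-truth
Log S linear in calculated log P (coefficient −1) and molecular weight
(−0.003) with an affine calibration to mean −3.5 / SD 1.8 — the bulk of
real curated sets — and the *effective* post-calibration coefficients
recorded for recovery tests. The resulting class histogram is dominated by
classes 5–6 without any explicit skew parameter. Records are emitted with
N(0, 0.5) observation noise (the interlaboratory error), 2–5 copies for a
configurable fraction of compounds (default 0.5), 2% gross outliers of
±(2–4) log units, and randomized units.

A descriptor-linear truth makes parameter recovery exactly testable and
mirrors the empirical dominance of hydrophobicity over aqueous solubility,
but it is not a physical model: real solubility has crystal-packing,
ionization and temperature effects no descriptor-linear function captures.
Passing the synthetic benchmarks therefore certifies the machinery —
curation arithmetic, leak-free stacking, AD coverage, triage ordering —
not laboratory accuracy.

## Benchmark problem sizes

The statistical acceptance checks run at the sizes the properties are
stated for: AD self-coverage and the end-to-end recovery benchmark at
n = 2000 compounds (1600 train / 400 held out; held-out RMSE must land in
[0.5, 0.65] against observations carrying 0.5 noise), stacking dominance at
n = 1000 over 20 seeds (stacking CV RMSE within +0.02 of the best base),
the merge oracle over 1000 random lists, and reliability ordering pooled
over 10 query seeds mixing held-out in-domain molecules with heavier
out-of-grammar molecules (MW 400–650), comparing only groups with at least
20 pooled members (the mean of a near-empty group is noise).

## Known limitations

- The Euclidean AD aggregates "similarity to the training set" as distance
  to the centroid: O(1) per query and monotone, but blind to multi-modal
  training distributions (the k-NN variant covers that at higher cost).
- The density AD inherits t-SNE's seed dependence; thresholds are
  reproducible only with the stored embedding seed.
- Two-record outliers survive curation by design (see above).
- Borderline re-sampling falls back to plain SMOTE when no danger points
  exist, rather than erroring.
- The CLI persists models with joblib; archives are not portable across
  major library versions.
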