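# Methods

This note documents the model, the synthetic data it is validated on, the
numerical choices, and what the tests do and do not demonstrate.

## Model

### Encoding

Raw records mix 14 string-typed and 19 numeric attributes.  Categorical
columns are mapped through an ordered vocabulary (sorted lexicographically,
fitted on training rows only) and expanded one-hot, so every pair of
distinct categories sits at Euclidean distance √2; a category unseen at fit
time encodes as an all-zero block rather than an error, keeping prediction
total.  Numeric columns are standardized with training-set mean and
*population* standard deviation; missing numeric values are imputed with the
training mean (standardizing to 0); a constant column is flagged and encoded
as zeros.

The content field carries a unit tag, so it is decomposed into three derived
features before standardization:

* `content_mass_mgkg` — mass concentrations on a common mg/kg scale
  (μg/kg ÷ 1000), zero for count units;
* `content_count_log10` — microbial counts (CFU/g, MPN/g) on a log10(1+x)
  scale, zero for mass units;
* `hazard_quotient_log` — log1p of content divided by the record's health
  guidance value.  The hazard quotient (measured content relative to its
  guidance limit) is the standard first step of chemical risk
  characterization and is unit-free because both terms share the record's
  unit.

The calendar month of production becomes a month index counted from 2015-01.
With the default vocabularies the encoded width is M = 109.

### Padded multigranularity scanning

A width-M vector is re-represented by sliding windows of lengths
k ∈ {2, 4, 8}.  Without padding the edge features are under-sampled (index 0
appears in exactly one stride-1 window); padding both ends with k−1 zeros
gives every original feature exactly k windows.  Window counts are
M′ = M − k + 1 (unpadded) and M′ = ⌊(M + k − 2)/s⌋ + 1 (padded); when the
stride does not divide the span the last partial step is dropped.  Scanning
runs after standardization, so the padding value 0 equals the training
column mean — intentional.

Per granularity, two window-level forests (one fully random extra-trees with
a single candidate feature per split, one standard bagged forest) are
trained on the pooled (sample × window) rows, each window inheriting its
sample's label; pooled training rows are subsampled to a cap of 100,000 per
forest.  Each window is scored into a P-vector of class probabilities, and
concatenation over windows, forests and granularities yields
Σ_g M′_g·P·F output columns.

Two implementation details matter for honest stacking:

* **Out-of-fold scan features.**  Window forests fitted on all training rows
  would hand the cascade partially memorized probabilities for those same
  rows, inflating layer accuracies.  Training-row features therefore come
  from 3-fold fold-local forests that never saw the row.
* **Fold-averaged inference.**  New samples are scored by the average of the
  fold forests rather than by a refit-on-all forest, so inference features
  share the calibration of the training features.  (An all-row refit is
  sharper than a fold model; mixing the two was measured to cost several
  accuracy points downstream.)

The default stride is 4.  Stride 1 is fully supported (and is what the
equal-coverage property uses), but the stride-1 representation is ~16× wider
than the encoded input; at benchmark scale the narrower default preserved
held-out accuracy while keeping a full training run in minutes on one CPU.

### K-fold stacked cascade

Each layer holds a roster of four base learners mirroring the model families
the method is usually compared against:

| learner | key settings |
|---|---|
| extra-trees | 30 trees, √M features per split |
| random forest | 30 trees, √M features per split |
| hist gradient boosting | 15 rounds, 30% feature fraction, 64 bins |
| logistic regression | lbfgs, 40 iterations |

Per layer, a stratified K-fold partition (K = 5 by default; per-class fold
sizes differ by at most one) yields out-of-fold class probabilities: the
prediction for each sample comes from models trained on the other K−1 folds.
The layer evaluation is E = (1/K)·Σ_i E_i, where E_i is the fold-i accuracy
of the roster-averaged out-of-fold prediction.  After extraction each
learner is refit on all rows for inference.  A learner whose fit raises is
replaced by a uniform-probability fallback with a warning so the layer stays
total.

Layer l+1 consumes the *original* input (encoded features ⊕ scan features)
concatenated with layer l's outputs only — not a cumulative concatenation —
so the input width is constant across depths.  Growth continues while E
improves by more than 1e-4 with patience 1, up to 3 layers by default; the
retained depth maximizes traced E.  The cap of 3 (rather than a larger
ceiling) reflects that on the synthetic benchmark E plateaus by the third
layer while each additional layer costs K+1 roster fits; the cap is a plain
config field.

Architecture 1 (the ablation baseline) skips scanning and replaces the
K-fold machinery with a single stratified 90/10 hold-out split: layers are
fitted on the 90% part, E is the hold-out accuracy, and fusion is fitted on
hold-out scores.

### Gaussian-mixture fusion

The final layer's n component classifiers each emit per-class probability
scores.  Scores are first standardized per column to zero mean and unit
variance over the fitting set — the "1×1 convolution + batch normalization"
stage: an affine per-column map with no cross-column mixing, statistics
frozen for inference.  The batch-size hyperparameter is the chunk size of
this accumulation; chunks are merged exactly, so it affects memory, not
results.

For component i and class c, a scalar Gaussian N(μ_ic, σ_ic²) models the
standardized score component i assigns to the true class on class-c training
rows.  EM maximizes the mixture log-likelihood

    ℓ = Σ_j log Σ_i w_i N(y_ji; μ_{i,c_j}, σ_{i,c_j}²)

with responsibilities γ_ji ∝ w_i N(·) normalized over components, weight
updates w_i = (1/m)Σ_j γ_ji, and γ-weighted mean/variance updates per
(component, class).  Iteration stops when |Δℓ| < 1e-6 or after `epochs`
iterations (default 100); variances are floored at 1e-6; the trace is
recorded and is non-decreasing by the EM guarantee.

Initialization places μ_ic at the ((i+0.5)/n)-quantile of component i's own
class-c observations with moment-based variances and uniform weights.  The
quantile stagger (rather than plain per-component moments) matters in the
degenerate case of identically scoring components, which would otherwise
start symmetric and never separate; for distinct components it is close to
the moment initialization.  A seeded random initialization is available for
robustness testing.

Prediction fuses raw component probabilities, p_c ∝ Σ_i w_i p_ic,
renormalized across classes; argmax ties resolve to the lowest class index.
This fusion is a weighted vote: it cannot exceed a dominant component by
much, but the EM weights measured on the benchmark concentrate on the most
reliable components (see `examples/05_gaussian_fusion.py`).

## Synthetic data

The generator emulates a proprietary grain-monitoring database: the full
schema above, 18 hazards with plausible per-hazard regulatory limits shipped
as configuration (they are parameters, not claims about any national
standard), environment fields uniform within their physical ranges, and an
eight-level label whose default per-level counts are
15566, 3752, 1288, 2117, 2575, 1726, 1386, 5760 (34,170 records; `scaled(n)`
preserves the proportions by largest-remainder rounding).

Ground truth is rule-based and hierarchical.  Each record receives

* an exceedance grade e ∈ 0..4 — its hazard quotient digitized at
  0.5 / 1 / 2 / 5 (the record's health guidance value is its hazard's limit);
* an environment grade v ∈ 0..2 — temperature outside 10–25 °C, relative
  humidity above 65% (the two dominant storage-risk drivers for grain;
  light, O₂ and CO₂ are monitored but act as realistic nuisance);
* a link grade l ∈ 0..2 — production > circulation > sale, encoding that
  front-end links carry more risk;
* a dangerousness grade x ∈ 0..2 — high/severe toxicity, IARC group 1/2A
  carcinogenicity.

The latent score is z = w1·e + 0.9·w1·(w2·v/2 + w3·l/2 + w4·x/2)/(w2+w3+w4)
+ 0.01·log1p(quotient) + Gaussian noise, with default weights
(1.0, 0.5, 0.4, 0.3) and noise at 0.5% of the deterministic spread.  The
exceedance grade dominates; the other rules order records within a grade;
the small quotient term breaks remaining ties monotonically, so with
weights (1,0,0,0) and no noise the level is an exactly monotone step
function of the quotient.  Labels are assigned by ranking z and cutting at
the cumulative level counts — per-level counts are therefore *exact* — after
which a label-noise rate η (default 0.02) shifts that fraction of labels by
one level.

This construction was calibrated once so the data are learnable in the sense
the benchmark requires — a single 40-tree bagged forest reaches ≥ 0.8
held-out accuracy at n = 10,000, leaving headroom for the stacked network —
while keeping an irreducible error floor from η and the latent noise.

**What the generator does not emulate:** real covariance between province,
season and hazard; reporting artifacts and missing data; drifting limits;
free-text fields.  Passing benchmarks on this data shows the pipeline learns
rule-based structure with an observable driver under class imbalance and
label noise; it does not certify performance on any real database.

## Benchmark problem sizes

The packaged evaluation uses sizes chosen to exercise the method at
realistic scale while a full run stays within desk-scale compute budgets
(single CPU, minutes):

* main benchmark: n = 10,000, 90/10 stratified split, η = 0.02, fixed seed —
  the full architecture against each roster member trained alone on the same
  encoded features;
* architecture ordering: mean held-out accuracy over 5 seeds at n = 1,500
  with depth capped at 2, Architecture 2 vs Architecture 1;
* reproducibility: the whole pipeline run twice at n = 600 under one master
  seed, compared bit-for-bit;
* EM recovery: m = 5,000 draws from a ½N(0,1) + ½N(3,1) mixture.

Seeds fan out from one master seed through `numpy.random.SeedSequence`, so
every stage (generation, splitting, fold assignment, forests, fusion
initialization) is reproducible.

## Known limitations

* The fusion is a weighted linear vote; a meta-learner could in principle
  exceed the best component, the vote cannot by much.
* The cascade retains the E-maximizing depth but E is an out-of-fold
  estimate; on small data its variance can pick a slightly suboptimal depth.
* Scanning treats column order as meaningful within windows; for tabular
  data the order is arbitrary, and the benefit comes from the forest
  re-representation rather than locality.  This matches the measured result
  that scanning helps the weaker components far more than the strongest one.
* Logistic regression runs a capped 40 lbfgs iterations; on wide scanned
  inputs it may stop short of full convergence (by design, for bounded
  runtime — raise `lr_max_iter` if exact convergence matters).
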