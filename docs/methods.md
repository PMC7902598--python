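# Methods

## The problem

Clinical endpoint prediction for cancer patients draws on two very different
kinds of data: a handful of strong, heterogeneous clinical variables
(age, stage, grade, receptor status, …) and one or more omics layers
(expression, copy number, methylation, protein arrays) containing thousands
of features that are individually weak and strongly inter-correlated.
Concatenating them ("early integration") fails in practice: a tree ensemble
offered ten strong clinical columns next to a hundred weak molecular ones
almost never splits on the molecular ones, so the merged model collapses to
the clinical model.  Stacking separate models ("late integration" / super
learning) works but is opaque and computationally heavy.

`clinomix` implements the hybrid alternative: each omics layer is first
compressed into a single *synthetic variable* — the per-sample out-of-bag
(OOB) positive-vote fraction of a random forest trained on that layer's
selected features — and the synthetic columns are appended to the clinical
table before fitting one final random forest.  Because OOB votes come only
from trees whose bootstrap sample excluded the sample in question, the
synthetic variable is an internally cross-validated prediction: it is
comparable in strength to a clinical variable and can be computed on the
training set without leaking labels.  Each training sample is out of the
bag for a fraction `e⁻¹ ≈ 0.368` of the trees, so the vote fraction is an
average over roughly `n_trees/e` trees.

## Pipeline stages

### Preprocessing (`clinomix.preprocess`)

Missing molecular values are imputed per feature by the mean or median of
the observed values.  An optional log2 transform precedes filtering (values
≤ 0 are an error).  The prefilter keeps a feature only if

1. **intensity** — at least `min_fraction_above` (default 10%) of samples
   exceed the threshold `T`, the `intensity_quantile` (default first
   quartile) of the distribution of per-feature maxima; and
2. **variation** — its robust coefficient of variation
   `IQR / (1.349·|median|)` exceeds `robust_cv_min` (default 0.05).

A feature with zero IQR gets robust CV 0 (always dropped by criterion 2); a
variable feature whose median is exactly 0 gets +∞ (never dropped by it).
`T` uses NumPy's linear-interpolation quantile; at small feature counts the
kept set can depend on this convention.  `T` is conceptually a property of
the full cohort: re-applying the filter to an already filtered table with
`T` held (`intensity_threshold=...`) is the identity, whereas recomputing
`T` on the survivors raises it and drops more features — the filter is
idempotent only under a held threshold, which is how it should be re-applied.

### Feature selection (`clinomix.selection`)

Molecular features are ranked by the p-value of one of three filters
(ties broken by descending score, then name, for reproducibility):

* **U-test** — two-sided Mann–Whitney; exact null distribution when
  n ≤ 20 and the feature is tie-free, normal approximation with tie
  correction otherwise; constant features get p = 1 by convention.
* **MDFS-1D** — information gain `IG(f) = H(Y) − H(Y | disc(f))`,
  maximised over `n_discretizations = 30` random cuts of the feature into
  `n_bins = 2` bins (split quantiles drawn uniformly from (0.25, 0.75)).
  Features with ≤ `n_bins` distinct values are used as-is.
* **MDFS-2D** — the conditional gain attributed to `f` within its best
  pair, `max_g [H(Y|g) − H(Y|f,g)]`; detects pure interactions (XOR) that
  are invisible to any one-dimensional filter.

MDFS p-values use the asymptotic χ² distribution of the likelihood-ratio
statistic `2·N·IG` (nats) with `df = n_bins − 1` (1D) or
`(n_bins − 1)·n_bins` (2D — one set of bin contrasts per conditioning
cell).  This is an asymptotic approximation, not exact at small n, and the
maximisation over random discretizations makes the p-values slightly
anti-conservative; they are used for ranking and for the SGoF count, both
of which tolerate this.

Multiple testing uses **SGoF** (sequential goodness of fit): with
`F = #{p ≤ γ}`, while a one-sided binomial test of `F` successes in `n`
trials at rate `γ` is significant at level `α`, the smallest undeclared
p-value is declared significant and `F` decremented.  SGoF maximises power
at the price of a liberal (~10%) false-positive fraction under the null —
the right trade-off when a forest downstream is robust to some noise
features.

Redundancy is pruned greedily: walking the ranking, a feature is kept only
if its |Spearman ρ| (average ranks for ties) with every already-kept
feature is below `rho_max = 0.7`; the kept set is capped at the top
`m_cap = 100`.  The stage order is rank → SGoF → redundancy → cap, and the
reported `n_after_redundancy` is the count at termination (equal to the cap
when the walk stops early).

Clinical tables use an all-relevant shadow-feature selector instead: at
each iteration every feature gets a permuted shadow copy, a forest is
trained on the augmented table, and a feature scores a hit when its
importance exceeds the maximum shadow importance; two-sided binomial tests
(Bonferroni-corrected across features) confirm or reject.  Importance is
the forest's impurity importance — the default of the widely used Python
implementation of this algorithm and ~50× cheaper than permutation
importance; with the sharp relevant/irrelevant border typical of clinical
variables the two agree.  Clinical selection is run once on the full data
set (few variables, sharp border); this can give the clinical-only baseline
a small optimistic bias, which makes the measured *gain* of integrated
models slightly conservative.

### Forest models (`clinomix.rf_modeling` surface in `forest.py`)

`scikit-learn`'s `RandomForestClassifier` stands behind the forest
(bootstrap bagging, √p features per split, default `n_trees = 500`; the
per-fold evaluation forests in the test-suite use fewer trees).  OOB
bookkeeping is done on top of it with hard per-tree votes (not averaged
probabilities): for each tree, the samples absent from its bootstrap sample
receive its vote.  Samples never OOB (possible at very small `n_trees`)
get fraction 0.5 and a warning.  An `inbag_positive_fraction` is recorded
purely as a leakage diagnostic — building a synthetic variable from in-bag
votes on the full data is the canonical mistake, and the test suite checks
that it (and only it) breaks the null-calibration band.

The decision cutoff on the vote fraction is tuned to maximise MCC over the
grid of midpoints between consecutive distinct OOB scores plus 0.5; MCC
ties break toward the cutoff closest to 0.5, then the smaller one.  The
degenerate all-equal-scores case returns 0.5.  MCC is defined as 0 when a
confusion marginal is zero.

### Evaluation (`clinomix.evaluate`)

`r` repeats (default 30) of stratified `k`-fold CV (default 5).  All
feature selection and model fitting happen inside the training fold (the
clinical all-relevant set is the single documented upstream exception).
AUC uses the tie-aware Mann–Whitney form on raw vote fractions; ACC/MCC use
the fold's own tuned cutoff.  Strategies are compared by a paired
one-sided t-test on per-repeat mean AUC (repeat means, not fold values,
to respect within-repeat dependence), with the count of repeats won.
Zero-variance difference vectors use conventions: identical → t = 0,
p = 0.5; constant shift → p = 0 or 1.

### Integration (`clinomix.integration`)

* **Early**: clinical ∪ top-m molecular columns, one forest.
* **Hybrid**: per layer — select, train a layer forest, take its OOB vote
  fraction as the synthetic column (one synthetic variable per layer ×
  filter; the default uses MDFS-1D, the computationally efficient filter);
  final forest on clinical + synthetic columns; cutoff from the final
  model's OOB scores.  A layer with an empty selection is skipped with a
  warning; with no layers the hybrid reduces exactly to the clinical-only
  model.  For new samples the stored layer forests predict the synthetic
  columns (Algorithm: fit on train, predict vote fractions on test).
* **Super learner**: per internal-CV loop (default 30 loops of stratified
  5-fold CV), out-of-fold base-model predictions form a meta-feature
  matrix and a combiner is fitted; the eventual prediction is the average
  of the loop-level combined models applied to meta-features from base
  models refitted on the full training set.  Combiners: non-negative least
  squares (no intercept, weights renormalised to sum 1, predictions
  clipped to [0,1]), a random forest, or the unweighted mean of the `k`
  base models with the highest training AUC (`best_k`; `k` = all reduces
  to the simple mean).
* **BBC** (bootstrap bias correction): the combiner's generalisation
  performance is estimated from a single internal-CV run by `B` (default
  30) bootstrap draws — fit the combiner on in-bag meta-rows, evaluate on
  out-of-bag rows, average.  Draws with a single-class out-of-bag part are
  redrawn (bounded retries).  ACC/MCC use a cutoff tuned on the in-bag
  predictions.

### Sensitivity analysis (`clinomix.sensitivity`)

Removal-based importance: ΔAUC(f) = mean AUC(full) − mean AUC(−f) under
identical repeated-CV partitions, with sd from the per-repeat paired
differences.  RFE removes the feature with the smallest ΔAUC (ties:
lexicographic) and rebuilds; the faithful mode recomputes the
leave-one-out importances at every step, a cheap mode ranks once on the
full set and only re-evaluates the shrinking model.  The recommended
compact model is the smallest size whose mean AUC is within one full-model
sd of the full model — an operationalisation of the usual "red line" on
RFE plots.  Two perfectly redundant features mask each other in the
one-at-a-time analysis (each ΔAUC ≈ 0); RFE resolves the masking by
removing one copy with no performance drop.

## The synthetic cohort generator

The generator (`clinomix.synthetic`) emulates the statistical structure
the method assumes, conditional on `y ~ Bernoulli(positive_fraction)`:

* continuous clinical feature with effect `d`: `N(d·y, 1)` — used alone as
  a score its AUC is `Φ(d/√2)`;
* ordinal/categorical clinical features: equal-frequency binning of such a
  latent into `n_levels` integer codes (qualitative clinical data is
  assumed numerically encoded);
* omics layers: features partitioned into clusters; cluster members share
  a latent factor giving within-cluster correlation `c`
  (`√c·z + √(1−c)·ε`), and members of informative clusters get a `d·y`
  shift.  The shift is applied so the realised per-feature marginal shift
  equals `d` for any `c`.  Informative features occupy whole clusters, so
  irrelevant features never carry a class shift;
* redundant clinical pairs via a Gaussian copula
  (`ρ_pearson = 2·sin(π·ρ_spearman/6)`), hitting the target Spearman
  correlation empirically within ±0.05;
* missing entries as NaN, uniformly at random; imputation is left to
  preprocessing.

Two reference configurations define the study-like conditions used by the
tests and the acceptance script.  `signal_cohort_config`: n = 400 (tests
use 300), positive fraction 0.45, four informative clinical features
(effects 1.0, 0.7, 0.6, 0.5; mixed continuous/ordinal), four clinical
noise features, one redundant pair at Spearman 0.82, and a "GE" layer in
which half the features are informative with per-feature effect 0.15
(individual AUC ≈ 0.54) in clusters of ~5 at correlation 0.5 — strong
clinical signal, individually weak but collectively informative molecular
signal; the effect size is calibrated so the layer-only model's AUC sits
roughly 0.05–0.08 below the clinical-only model's, the relative strength
typically observed for expression layers next to clinical data.  `null_cohort_config` is the same skeleton with every effect set
to 0.  Cluster size ~5 keeps the number of independent informative
directions high enough that the layer's aggregate information is stable
across cohort draws; with few large clusters the shared latents dominate
and the realised omics signal varies strongly from seed to seed.

What the generator does **not** emulate: count-type or heavy-tailed
marginal distributions of real sequencing data, batch effects, platform
artefacts, survival times (the endpoint is binary), or dependence between
clinical and molecular features beyond what `y` induces.  Passing tests
therefore demonstrate the *statistical mechanics* of the method —
leakage-free synthetic variables, correct ordering of integration
strategies in the weak-molecular regime, recovery of planted ground truth —
not performance on any particular real cohort.

## Numerical and design choices

* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; derived seeds stay below 2³¹.  Identical
  seeds reproduce every table, model and metric bit-for-bit.
* Spearman correlations use average ranks; a constant column has ρ = 0
  against anything by convention.
* NNLS weight degeneracy (duplicate base models) is resolved by asserting
  predictions, not weights; if all weights are zero the combiner falls
  back to the uniform average.
* The paired t-test is one-sided (gain over baseline), pairing with the
  directional win counts.
* Test-suite and acceptance-script problem sizes (hundreds of samples,
  100–400 molecular features, 25–100 trees, 1–2 super-learner loops) are
  scaled-down analogues of the defaults (500 trees, 30 loops, m = 100);
  the package's defaults remain the full-size ones.

### Null calibration of cross-validated AUC

For a *fixed* finite sample of pure noise, the expectation of repeated-CV
AUC is not exactly 0.5: it carries a dataset-conditional offset (sd ≈
0.035 across n = 300 cohort draws in our measurements) that does not
shrink with more repeats.  Leakage guards therefore average the null
check over several independent null cohorts; a genuine label leak moves
the estimate to ≈ 0.9 and is unmistakable either way.

## Known limitations

* MDFS-2D is O(p²) per discretization and intended for candidate sets,
  not whole omics layers.
* The shadow-feature selector uses impurity importances, which can favour
  high-cardinality features; clinical tables with many-level categorical
  codes may need permutation importances (not implemented).
* BBC corrects the combiner-selection optimism only; it inherits whatever
  bias the base-model internal CV has.
* The recommended-model rule (within one sd of full) is a heuristic; on
  flat RFE traces it can be conservative by a feature or two.
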