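# clinomix

Hybrid integration of clinical and molecular (omics) data for binary
clinical-endpoint classification — for biostatisticians and computational
biologists who need to combine a handful of strong clinical predictors with
one or more high-dimensional omics layers (expression, copy number,
methylation, protein arrays) in a single, interpretable model.

## The method

Early integration (concatenating tables) fails on strongly heterogeneous
data: a random forest offered a few strong clinical columns next to a
hundred weak molecular ones essentially ignores the molecular block.  Late
integration (super learning on cross-validated base-model predictions)
works but is costly and opaque.  `clinomix` implements the hybrid strategy
between them:

1. per omics layer, rank features by a filter (Mann–Whitney U-test or the
   entropy-based MDFS filter in 1 or 2 dimensions), correct the p-values
   with SGoF, prune features with pairwise Spearman |ρ| ≥ 0.7 greedily, and
   cap at the top *m* = 100;
2. train a random forest on the selected features and record, for every
   training sample, the fraction of *out-of-bag* trees voting for the
   positive class (each sample is OOB for ≈ e⁻¹ of the trees).  This
   per-sample vote fraction — an internally cross-validated prediction in
   (0, 1) — is the layer's **synthetic variable**;
3. append the synthetic columns to the clinical table and fit one final
   random forest, tuning its vote cutoff to maximise the Matthews
   correlation coefficient (MCC) on its own OOB predictions.

Because the synthetic variable is OOB-based it can be computed on the
training set without label leakage, and because it is a single column of
clinical-variable strength, the final model can be probed by
single-feature-removal sensitivity analysis (ΔAUC) and recursive feature
elimination, yielding compact models.

The package also provides the comparator strategies (early merge; super
learning with NNLS / random-forest / best-k combiners and bootstrap bias
correction), a repeated stratified k-fold cross-validation harness with
paired t-test comparisons, a Boruta-style all-relevant selector for
clinical tables, molecular preprocessing (imputation, log2,
intensity/variation prefilter), and a synthetic-cohort generator with known
ground truth so the whole pipeline is testable without external data.

## Worked example

```python
from clinomix import (
    CVConfig, ClinicalOnlyStrategy, HybridStrategy, SelectionConfig,
    compare_strategies, generate_cohort, repeated_cv,
)
from clinomix.synthetic import signal_cohort_config

# a study-like cohort: strong clinical signal, one omics layer of
# individually weak but collectively informative features
cfg = signal_cohort_config(n_samples=300, seed=42, n_omics_features=300)
clinical, (ge,), y, truth = generate_cohort(cfg)

cv = CVConfig(r=10, k=5, seed=17)
fs = SelectionConfig(method="mdfs1d")
rec_clin = repeated_cv(clinical, {"GE": ge}, y, ClinicalOnlyStrategy(n_trees=60), cv)
rec_hyb = repeated_cv(clinical, {"GE": ge}, y, HybridStrategy(fs, n_trees=60), cv)

print(f"clinical-only AUC {rec_clin['auc'].mean():.3f}")
print(f"hybrid        AUC {rec_hyb['auc'].mean():.3f}")
cmp = compare_strategies(rec_hyb, rec_clin)
print(f"paired one-sided t = {cmp.t_statistic:.2f}, p = {cmp.p_value:.2g}, "
      f"wins = {cmp.wins}/{cmp.n_repeats}")
```

Output:

```
clinical-only AUC 0.813
hybrid        AUC 0.823
paired one-sided t = 3.55, p = 0.0031, wins = 9/10
```

The hybrid model's gain of ~0.01 AUC over the clinical baseline is small
but consistent across cross-validation repeats — it wins 9 of 10 repeats
and the paired t-test on per-repeat means is significant — which is the
signature of a weak but real, independent molecular signal.  Early
integration of the same data shows no gain (the weak molecular columns are
drowned out by the strong clinical ones), which is precisely the failure
mode the synthetic-variable construction avoids.

A command-line interface mirrors the library:

```bash
clinomix simulate --config cohort.yaml --out-dir cohort/
clinomix preprocess --table cohort/GE.csv --impute mean --out clean.csv
clinomix select --table clean.csv --decision cohort/decision.csv --method mdfs1d --out selected.tsv
clinomix evaluate --data-dir cohort/ --strategies clinical,hybrid --r 30 --k 5 --seed 7 --out-dir results/
```

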