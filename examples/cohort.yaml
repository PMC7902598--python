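# Example synthetic-cohort configuration for `clinomix simulate`.
# Strong heterogeneous clinical predictors (one strongly related pair),
# one omics layer of weak cluster-correlated features, moderate imbalance.
n_samples: 300
positive_fraction: 0.45
clinical_spec:
  - {name: age,   kind: continuous, effect_size: 1.0}
  - {name: npi,   kind: continuous, effect_size: 0.7}
  - {name: stage, kind: ordinal,    effect_size: 0.6, n_levels: 4}
  - {name: grade, kind: ordinal,    effect_size: 0.5, n_levels: 3}
n_clinical_noise: 4
redundant_pairs:
  - [npi, 0.82]
omics_specs:
  - name: GE
    n_features: 300
    n_informative: 150
    effect_size: 0.15
    n_clusters: 60
    within_cluster_correlation: 0.5
    missing_rate: 0.02
seed: 0
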