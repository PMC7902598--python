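"""Single-feature-removal ΔAUC analysis and recursive feature elimination.

The combined (clinical + synthetic) model has few enough features that
importance can be measured the direct way: rebuild the model without the
feature, under the same repeated-CV partitions, and record the drop in
mean AUC.  Recursive feature elimination then iteratively removes the
least important feature, yielding an AUC trace and a compact recommended
model (the smallest size whose mean AUC stays within one standard
deviation of the full model's).

Two perfectly redundant features mask each other in the one-at-a-time
analysis — each has ΔAUC ≈ 0 despite their joint importance — but RFE
recovers: it removes one copy without any performance drop and the
survivor's importance then becomes visible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .evaluate import CVConfig, Strategy, repeated_cv, per_repeat_mean
from .tables import FeatureTable

__all__ = ["SensitivityReport", "RfeTrace", "loo_sensitivity", "rfe", "forest_builder", "hybrid_builder"]

StrategyBuilder = Callable[[frozenset], Strategy]


@dataclass
class SensitivityReport:
    """Per-feature ΔAUC = AUC(full) − AUC(without feature), sd across repeats."""

    table: pd.DataFrame  # columns: feature, delta_auc, sd — sorted by delta_auc desc
    full_auc_mean: float
    full_auc_sd: float

    def delta(self, feature: str) -> float:
        return float(self.table.set_index("feature").loc[feature, "delta_auc"])

    def sd(self, feature: str) -> float:
        return float(self.table.set_index("feature").loc[feature, "sd"])


@dataclass
class RfeTrace:
    """Elimination order with the AUC (mean ± sd over repeats) at each size."""

    trace: pd.DataFrame  # columns: size, removed_feature, auc_mean, auc_sd
    feature_sets: dict[int, list[str]]
    recommended_size: int
    recommended_features: list[str]


def forest_builder(n_trees: int = 200, name: str = "forest"):
    """Builder for a plain clinical-table forest over a feature subset."""
    from .integration import ClinicalOnlyStrategy

    def build(excluded: frozenset, all_features: Sequence[str]) -> Strategy:
        feats = [f for f in all_features if f not in excluded]
        return ClinicalOnlyStrategy(n_trees=n_trees, clinical_features=feats, name=name)

    return build


def hybrid_builder(fs_config=None, n_trees: int = 200):
    """Builder for the hybrid strategy over clinical features and omics layers.

    Feature names are the clinical column names plus the omics layer names;
    excluding a layer name removes its synthetic variable.
    """
    from .integration import HybridStrategy
    from .selection import SelectionConfig

    fs_config = fs_config or SelectionConfig(method="mdfs1d")

    def build(excluded: frozenset, all_features: Sequence[str]) -> Strategy:
        return HybridStrategy(
            fs_config=fs_config,
            n_trees=n_trees,
            drop_clinical=set(excluded),
            drop_layers=set(excluded),
        )

    return build


def _auc_by_repeat(
    build, excluded: frozenset, features, clinical, omics, y, cv: CVConfig
) -> pd.Series:
    records = repeated_cv(clinical, omics, y, build(excluded, features), cv)
    return per_repeat_mean(records, "auc")


def loo_sensitivity(
    build: Callable,
    features: Sequence[str],
    clinical: FeatureTable,
    omics: dict[str, FeatureTable],
    y,
    cv: CVConfig = CVConfig(),
) -> SensitivityReport:
    """Leave-one-feature-out ΔAUC under identical repeated-CV partitions.

    ``build(excluded, features)`` must return a fresh strategy using all
    features except ``excluded``.  ΔAUC(f) and its sd are computed from
    the per-repeat paired differences.
    """
    features = list(features)
    if len(features) < 2:
        raise ValueError("need at least 2 features for leave-one-out sensitivity")
    full = _auc_by_repeat(build, frozenset(), features, clinical, omics, y, cv)
    rows = []
    for f in features:
        wo = _auc_by_repeat(build, frozenset({f}), features, clinical, omics, y, cv)
        d = (full - wo).to_numpy()
        rows.append((f, float(d.mean()), float(d.std(ddof=1)) if len(d) > 1 else 0.0))
    table = pd.DataFrame(rows, columns=["feature", "delta_auc", "sd"]).sort_values(
        ["delta_auc", "feature"], ascending=[False, True], ignore_index=True
    )
    return SensitivityReport(
        table=table,
        full_auc_mean=float(full.mean()),
        full_auc_sd=float(full.std(ddof=1)) if len(full) > 1 else 0.0,
    )


def rfe(
    build: Callable,
    features: Sequence[str],
    clinical: FeatureTable,
    omics: dict[str, FeatureTable],
    y,
    cv: CVConfig = CVConfig(),
    recompute: bool = True,
) -> RfeTrace:
    """Recursive feature elimination down to a single feature.

    At each step the feature with the smallest ΔAUC (ties: lexicographic)
    is removed and a new model is built.  With ``recompute=True`` (the
    faithful mode) the leave-one-out importances are recomputed at every
    step; ``recompute=False`` is a cheap mode that ranks once on the full
    set and then only re-evaluates the shrinking model.

    The recommended compact model is the smallest size whose mean AUC is
    at least the full model's mean minus one full-model sd.
    """
    features = list(features)
    if len(features) < 2:
        raise ValueError("need at least 2 features")
    current = list(features)
    rows = []
    sets: dict[int, list[str]] = {}

    cheap_order: list[str] | None = None
    if not recompute:
        rep = loo_sensitivity(build, features, clinical, omics, y, cv)
        cheap_order = rep.table.sort_values(["delta_auc", "feature"], ascending=[True, True])[
            "feature"
        ].tolist()

    while current:
        sets[len(current)] = list(current)
        if len(current) == 1:
            aucs = _auc_by_repeat(build, frozenset(set(features) - set(current)), features, clinical, omics, y, cv)
            rows.append((1, current[0], float(aucs.mean()), float(aucs.std(ddof=1)) if len(aucs) > 1 else 0.0))
            break
        if recompute:
            sub = loo_sensitivity(
                lambda excl, feats: build(frozenset(set(features) - set(current)) | excl, feats),
                current,
                clinical,
                omics,
                y,
                cv,
            )
            mean_auc, sd_auc = sub.full_auc_mean, sub.full_auc_sd
            worst = sub.table.sort_values(["delta_auc", "feature"], ascending=[True, True]).iloc[0][
                "feature"
            ]
        else:
            aucs = _auc_by_repeat(build, frozenset(set(features) - set(current)), features, clinical, omics, y, cv)
            mean_auc = float(aucs.mean())
            sd_auc = float(aucs.std(ddof=1)) if len(aucs) > 1 else 0.0
            worst = next(f for f in cheap_order if f in current)
        rows.append((len(current), worst, mean_auc, sd_auc))
        current.remove(worst)

    trace = pd.DataFrame(rows, columns=["size", "removed_feature", "auc_mean", "auc_sd"])
    full_mean = float(trace.iloc[0]["auc_mean"])
    full_sd = float(trace.iloc[0]["auc_sd"])
    ok = trace[trace["auc_mean"] >= full_mean - full_sd]
    recommended_size = int(ok["size"].min())
    return RfeTrace(
        trace=trace,
        feature_sets=sets,
        recommended_size=recommended_size,
        recommended_features=sets[recommended_size],
    )
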