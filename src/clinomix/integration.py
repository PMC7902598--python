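"""Integration strategies: early merge, hybrid OOB synthetic variables, super learning.

*Early integration* concatenates selected clinical and molecular features
into one table and hopes the classifier finds cross-set structure; with a
handful of strong clinical variables against many weak molecular ones, the
forest essentially ignores the molecular block.

*Hybrid integration* compresses each omics layer into a single synthetic
variable: a random forest trained on the layer's selected features yields
per-training-sample OOB positive-vote fractions — internally
cross-validated, hence comparable in strength to a clinical variable — and
these columns are appended to the clinical table before fitting the final
forest.  For new samples, each stored layer forest predicts the vote
fraction.

*Late integration* is a super learner: out-of-fold predictions of the base
models (one per data set × feature filter) from internal 5-fold CV form a
meta-feature matrix; a combiner (non-negative least squares, a random
forest, or the mean of the k best base models) is fitted per internal-CV
loop and predictions are averaged over loops.  Bootstrap bias correction
(BBC) estimates the combined model's generalisation performance from a
single internal-CV run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .evaluate import Strategy
from .forest import ForestModel, train_forest, predict_positive_fraction, tune_vote_cutoff
from .metrics import auc
from .selection import SelectionConfig, SelectedFeatureSet, select_features
from .tables import FeatureTable

__all__ = [
    "early_merge",
    "HybridModel",
    "hybrid_fit",
    "hybrid_predict",
    "fit_combiner",
    "bbc_estimate",
    "BaseModelSpec",
    "SuperLearnerModel",
    "superlearner_fit",
    "ClinicalOnlyStrategy",
    "SingleOmicsStrategy",
    "EarlyIntegrationStrategy",
    "HybridStrategy",
    "SuperLearnerStrategy",
]


def early_merge(clinical_selected: FeatureTable, molecular_top_m: FeatureTable) -> FeatureTable:
    """Column-wise concatenation of clinical and molecular tables, aligned by ID."""
    if set(clinical_selected.sample_ids) != set(molecular_top_m.sample_ids):
        raise ValueError("sample-ID mismatch between clinical and molecular tables")
    mol = molecular_top_m.data.loc[clinical_selected.sample_ids]
    collisions = [c for c in mol.columns if c in clinical_selected.data.columns]
    if collisions:
        mol = mol.rename(columns={c: f"{c}__{molecular_top_m.modality}" for c in collisions})
    return FeatureTable(pd.concat([clinical_selected.data, mol], axis=1), "merged")


# ---------------------------------------------------------------------------
# Hybrid integration


@dataclass
class HybridModel:
    layer_models: dict[str, tuple[SelectedFeatureSet, ForestModel]]
    final_model: ForestModel
    clinical_features: list[str]
    synthetic_names: list[str]
    skipped_layers: list[str] = field(default_factory=list)

    @property
    def tuned_cutoff(self) -> float:
        return self.final_model.tuned_cutoff


def _synthetic_name(layer: str, method: str) -> str:
    return f"synthetic_{layer}_{method}"


def hybrid_fit(
    clinical: FeatureTable,
    omics: dict[str, FeatureTable],
    y,
    fs_config: SelectionConfig = SelectionConfig(method="mdfs1d"),
    n_trees: int = 500,
    seed: int = 0,
) -> HybridModel:
    """Fit the hybrid model on training data.

    Per layer: select features, train a forest on them, and take its OOB
    positive-vote fraction as the layer's synthetic variable.  A layer with
    an empty selection is skipped with a warning.  The final forest is
    trained on clinical + synthetic columns and its cutoff tuned on its own
    OOB scores.
    """
    layer_models: dict[str, tuple[SelectedFeatureSet, ForestModel]] = {}
    skipped: list[str] = []
    synth_cols: dict[str, np.ndarray] = {}
    for i, (layer, table) in enumerate(omics.items()):
        cfg = replace(fs_config, seed=seed + i + 1)
        selected = select_features(table, y, cfg)
        if len(selected) == 0:
            warnings.warn(f"layer {layer}: empty selection, skipped", stacklevel=2)
            skipped.append(layer)
            continue
        fm = train_forest(table.select(selected.features), y, n_trees=n_trees, seed=seed + i + 1)
        layer_models[layer] = (selected, fm)
        synth_cols[_synthetic_name(layer, cfg.method)] = fm.oob_positive_fraction

    extended = clinical.data.copy()
    for name, values in synth_cols.items():
        extended[name] = values
    final = train_forest(FeatureTable(extended, "hybrid"), y, n_trees=n_trees, seed=seed)
    return HybridModel(
        layer_models=layer_models,
        final_model=final,
        clinical_features=clinical.feature_names,
        synthetic_names=list(synth_cols),
        skipped_layers=skipped,
    )


def hybrid_predict(
    model: HybridModel, clinical_new: FeatureTable, omics_new: dict[str, FeatureTable]
) -> np.ndarray:
    """Positive-vote fractions of the final model for new samples.

    Per stored layer, the layer forest predicts vote fractions for the new
    samples (the synthetic columns); the final forest then predicts on the
    extended clinical table.
    """
    extended = clinical_new.data.copy()
    for layer, (selected, fm) in model.layer_models.items():
        if layer not in omics_new:
            raise KeyError(f"missing omics layer at prediction time: {layer}")
        frac = predict_positive_fraction(fm, omics_new[layer])
        extended[_synthetic_name(layer, selected.method)] = frac
    return predict_positive_fraction(model.final_model, FeatureTable(extended, "hybrid"))


# ---------------------------------------------------------------------------
# Combiners and bootstrap bias correction


class _NNLSCombiner:
    """Non-negative least squares of y on the meta-features, no intercept.

    Weights are renormalised to sum to one so that the combined score of
    probability-like meta-features stays on the probability scale; the
    prediction is clipped to [0, 1].
    """

    kind = "nnls"

    def __init__(self, weights: np.ndarray):
        self.weights = weights

    def predict(self, meta: np.ndarray) -> np.ndarray:
        return np.clip(meta @ self.weights, 0.0, 1.0)


class _ForestCombiner:
    kind = "forest"

    def __init__(self, clf: RandomForestClassifier):
        self.clf = clf

    def predict(self, meta: np.ndarray) -> np.ndarray:
        pos = int(np.flatnonzero(self.clf.classes_ == 1)[0])
        return self.clf.predict_proba(meta)[:, pos]


class _BestKCombiner:
    """Unweighted mean of the k base models with the highest training AUC."""

    kind = "best_k"

    def __init__(self, columns: np.ndarray):
        self.columns = columns

    def predict(self, meta: np.ndarray) -> np.ndarray:
        return meta[:, self.columns].mean(axis=1)


def fit_combiner(
    meta: np.ndarray,
    y,
    kind: Literal["nnls", "forest", "best_k"] = "nnls",
    k: int | None = None,
    seed: int = 0,
    n_trees: int = 200,
):
    """Fit a second-level combiner on the meta-feature matrix (columns = base models)."""
    meta = np.asarray(meta, dtype=float)
    y = np.asarray(y)
    if meta.ndim != 2:
        raise ValueError("meta-feature matrix must be 2-D")
    if kind == "nnls":
        w, _ = nnls(meta, y.astype(float))
        total = w.sum()
        w = w / total if total > 0 else np.full(meta.shape[1], 1.0 / meta.shape[1])
        return _NNLSCombiner(w)
    if kind == "forest":
        clf = RandomForestClassifier(
            n_estimators=n_trees, max_features="sqrt", random_state=seed, n_jobs=1
        ).fit(meta, y)
        return _ForestCombiner(clf)
    if kind == "best_k":
        if k is None:
            k = meta.shape[1]
        if k > meta.shape[1]:
            raise ValueError(f"k={k} exceeds the number of base models {meta.shape[1]}")
        aucs = np.array([auc(meta[:, j], y) for j in range(meta.shape[1])])
        order = np.lexsort((np.arange(meta.shape[1]), -aucs))
        return _BestKCombiner(np.sort(order[:k]))
    raise ValueError(f"unknown combiner kind: {kind!r}")


def bbc_estimate(
    meta: np.ndarray,
    y,
    kind: Literal["nnls", "forest", "best_k"] = "nnls",
    B: int = 30,
    k: int | None = None,
    seed: int = 0,
    max_retries: int = 100,
) -> dict[str, float]:
    """Bootstrap-bias-corrected performance of a combiner on one internal-CV run.

    For each of ``B`` bootstrap draws of sample indices the combiner is
    fitted on the in-bag meta-rows and evaluated on the out-of-bag rows;
    the mean out-of-bag AUC/ACC/MCC over draws is the bias-corrected
    estimate.  Draws whose out-of-bag part is single-class are redrawn
    (bounded retries).
    """
    from .metrics import accuracy, mcc_from_labels

    if B < 10:
        raise ValueError("B must be >= 10")
    meta = np.asarray(meta, dtype=float)
    y = np.asarray(y)
    n = len(y)
    rng = np.random.default_rng(seed)
    aucs, accs, mccs = [], [], []
    for _ in range(B):
        for attempt in range(max_retries):
            idx = rng.integers(0, n, size=n)
            oob = np.setdiff1d(np.arange(n), idx)
            if oob.size > 0 and len(np.unique(y[oob])) == 2 and len(np.unique(y[idx])) == 2:
                break
        else:
            raise RuntimeError("could not draw a bootstrap sample with two-class OOB part")
        comb = fit_combiner(meta[idx], y[idx], kind=kind, k=k, seed=int(rng.integers(2**31 - 1)))
        scores_in = comb.predict(meta[idx])
        cut, _ = tune_vote_cutoff(np.clip(scores_in, 0, 1), y[idx])
        scores = comb.predict(meta[oob])
        pred = (scores > cut).astype(int)
        aucs.append(auc(scores, y[oob]))
        accs.append(accuracy(pred, y[oob]))
        mccs.append(mcc_from_labels(pred, y[oob]))
    return {"auc": float(np.mean(aucs)), "acc": float(np.mean(accs)), "mcc": float(np.mean(mccs))}


# ---------------------------------------------------------------------------
# Base models and super learner


@dataclass(frozen=True)
class BaseModelSpec:
    """One base model: a data set (clinical or a named omics layer) × a filter."""

    name: str
    layer: str | None = None  # None -> clinical table
    fs_config: SelectionConfig | None = None  # None -> use all features (clinical)


class _FittedBase:
    def __init__(self, spec: BaseModelSpec, model: ForestModel | None, features: list[str] | None):
        self.spec = spec
        self.model = model  # None when the layer selection was empty
        self.features = features

    def predict(self, clinical: FeatureTable, omics: dict[str, FeatureTable]) -> np.ndarray:
        table = clinical if self.spec.layer is None else omics[self.spec.layer]
        if self.model is None:
            return np.full(table.n_samples, 0.5)
        return predict_positive_fraction(self.model, table)


def _fit_base(
    spec: BaseModelSpec,
    clinical: FeatureTable,
    omics: dict[str, FeatureTable],
    y,
    n_trees: int,
    seed: int,
) -> _FittedBase:
    table = clinical if spec.layer is None else omics[spec.layer]
    if spec.fs_config is not None:
        selected = select_features(table, y, replace(spec.fs_config, seed=seed))
        if len(selected) == 0:
            return _FittedBase(spec, None, None)
        table = table.select(selected.features)
    fm = train_forest(table, y, n_trees=n_trees, seed=seed)
    return _FittedBase(spec, fm, table.feature_names)


@dataclass
class SuperLearnerModel:
    base_specs: list[BaseModelSpec]
    full_bases: list[_FittedBase]
    loop_combiners: list
    combiner_kind: str
    meta_feature_names: list[str]
    tuned_cutoff: float = 0.5

    def predict(self, clinical: FeatureTable, omics: dict[str, FeatureTable]) -> np.ndarray:
        meta = np.column_stack([b.predict(clinical, omics) for b in self.full_bases])
        preds = [c.predict(meta) for c in self.loop_combiners]
        return np.mean(preds, axis=0)


def superlearner_fit(
    clinical: FeatureTable,
    omics: dict[str, FeatureTable],
    y,
    base_specs: Sequence[BaseModelSpec],
    combiner: Literal["nnls", "forest", "best_k"] = "nnls",
    loops: int = 30,
    inner_k: int = 5,
    k_best: int | None = None,
    n_trees: int = 500,
    seed: int = 0,
) -> SuperLearnerModel:
    """Fit a super learner: internal-CV meta-features, one combiner per loop.

    Each loop runs a fresh stratified ``inner_k``-fold internal CV: base
    models (full feature selection + training) are fitted on the inner
    training split and predict the inner test split, giving out-of-fold
    meta-features for every training sample; the combiner is fitted on that
    matrix.  The eventual prediction for new data is the average of the
    loop-level combined models applied to meta-features from base models
    refitted on the full training data.
    """
    base_specs = list(base_specs)
    if len(base_specs) < 1:
        raise ValueError("need at least one base model")
    y_arr = np.asarray(y)
    n = clinical.n_samples
    ids = clinical.sample_ids
    rng = np.random.default_rng(seed)

    full_bases = [
        _fit_base(s, clinical, omics, y_arr, n_trees, seed=int(rng.integers(2**31 - 1)))
        for s in base_specs
    ]

    loop_combiners = []
    cv_preds = []  # per loop: combiner predictions on that loop's meta matrix
    for _ in range(loops):
        meta = np.full((n, len(base_specs)), np.nan)
        splitter = StratifiedKFold(
            n_splits=inner_k, shuffle=True, random_state=int(rng.integers(2**31 - 1))
        )
        for tr, te in splitter.split(np.zeros(n), y_arr):
            clin_tr, clin_te = clinical.restrict(ids[tr]), clinical.restrict(ids[te])
            om_tr = {k_: t.restrict(ids[tr]) for k_, t in omics.items()}
            om_te = {k_: t.restrict(ids[te]) for k_, t in omics.items()}
            for j, spec in enumerate(base_specs):
                fb = _fit_base(spec, clin_tr, om_tr, y_arr[tr], n_trees, seed=int(rng.integers(2**31 - 1)))
                meta[te, j] = fb.predict(clin_te, om_te)
        comb = fit_combiner(meta, y_arr, kind=combiner, k=k_best, seed=int(rng.integers(2**31 - 1)))
        loop_combiners.append(comb)
        cv_preds.append(comb.predict(meta))

    mean_cv_pred = np.clip(np.mean(cv_preds, axis=0), 0.0, 1.0)
    cutoff, _ = tune_vote_cutoff(mean_cv_pred, y_arr)
    return SuperLearnerModel(
        base_specs=base_specs,
        full_bases=full_bases,
        loop_combiners=loop_combiners,
        combiner_kind=combiner,
        meta_feature_names=[s.name for s in base_specs],
        tuned_cutoff=cutoff,
    )


# ---------------------------------------------------------------------------
# Strategy adapters for the CV harness


class ClinicalOnlyStrategy(Strategy):
    """Random forest on the clinical features alone (the baseline model)."""

    def __init__(self, n_trees: int = 500, clinical_features: list[str] | None = None, name: str = "clinical"):
        self.n_trees = n_trees
        self.clinical_features = clinical_features
        self.name = name

    def _restrict(self, clinical: FeatureTable) -> FeatureTable:
        if self.clinical_features is None:
            return clinical
        return clinical.select(self.clinical_features)

    def fit(self, clinical, omics, y, seed):
        self.model_ = train_forest(self._restrict(clinical), y, n_trees=self.n_trees, seed=seed)
        self.cutoff_ = self.model_.tuned_cutoff
        return self

    def predict_scores(self, clinical, omics):
        return predict_positive_fraction(self.model_, self._restrict(clinical))


class SingleOmicsStrategy(Strategy):
    """Feature selection + forest on one omics layer (no clinical features)."""

    def __init__(self, layer: str, fs_config: SelectionConfig = SelectionConfig(method="mdfs1d"), n_trees: int = 500):
        self.layer = layer
        self.fs_config = fs_config
        self.n_trees = n_trees
        self.name = layer

    def fit(self, clinical, omics, y, seed):
        table = omics[self.layer]
        selected = select_features(table, y, replace(self.fs_config, seed=seed))
        if len(selected) == 0:
            self.model_ = None
            self.cutoff_ = 0.5
            return self
        self.model_ = train_forest(table.select(selected.features), y, n_trees=self.n_trees, seed=seed)
        self.cutoff_ = self.model_.tuned_cutoff
        return self

    def predict_scores(self, clinical, omics):
        if self.model_ is None:
            return np.full(omics[self.layer].n_samples, 0.5)
        return predict_positive_fraction(self.model_, omics[self.layer])


class EarlyIntegrationStrategy(Strategy):
    """Merge clinical features with the top-m selected molecular features."""

    def __init__(
        self,
        fs_config: SelectionConfig = SelectionConfig(method="mdfs1d"),
        n_trees: int = 500,
        clinical_features: list[str] | None = None,
    ):
        self.fs_config = fs_config
        self.n_trees = n_trees
        self.clinical_features = clinical_features
        self.name = "early"

    def fit(self, clinical, omics, y, seed):
        if self.clinical_features is not None:
            clinical = clinical.select(self.clinical_features)
        merged = clinical
        self.selected_ = {}
        for i, (layer, table) in enumerate(omics.items()):
            selected = select_features(table, y, replace(self.fs_config, seed=seed + i + 1))
            self.selected_[layer] = selected.features
            if selected.features:
                merged = early_merge(merged, table.select(selected.features))
        self.model_ = train_forest(merged, y, n_trees=self.n_trees, seed=seed)
        self.cutoff_ = self.model_.tuned_cutoff
        return self

    def predict_scores(self, clinical, omics):
        if self.clinical_features is not None:
            clinical = clinical.select(self.clinical_features)
        merged = clinical
        for layer, feats in self.selected_.items():
            if feats:
                merged = early_merge(merged, omics[layer].select(feats))
        return predict_positive_fraction(self.model_, merged)


class HybridStrategy(Strategy):
    """Clinical features + per-layer OOB synthetic variables, one final forest."""

    def __init__(
        self,
        fs_config: SelectionConfig = SelectionConfig(method="mdfs1d"),
        n_trees: int = 500,
        clinical_features: list[str] | None = None,
        drop_layers: set[str] | None = None,
        drop_clinical: set[str] | None = None,
        name: str = "hybrid",
    ):
        self.fs_config = fs_config
        self.n_trees = n_trees
        self.clinical_features = clinical_features
        self.drop_layers = drop_layers or set()
        self.drop_clinical = drop_clinical or set()
        self.name = name

    def _prepare(self, clinical, omics):
        if self.clinical_features is not None:
            clinical = clinical.select(self.clinical_features)
        if self.drop_clinical:
            clinical = clinical.drop([f for f in self.drop_clinical if f in clinical.data.columns])
        omics = {k: v for k, v in omics.items() if k not in self.drop_layers}
        return clinical, omics

    def fit(self, clinical, omics, y, seed):
        clinical, omics = self._prepare(clinical, omics)
        self.model_ = hybrid_fit(
            clinical, omics, y, fs_config=self.fs_config, n_trees=self.n_trees, seed=seed
        )
        self.cutoff_ = self.model_.tuned_cutoff
        return self

    def predict_scores(self, clinical, omics):
        clinical, omics = self._prepare(clinical, omics)
        return hybrid_predict(self.model_, clinical, omics)


class SuperLearnerStrategy(Strategy):
    """Late integration via super learning inside the CV harness."""

    def __init__(
        self,
        base_specs: Sequence[BaseModelSpec],
        combiner: Literal["nnls", "forest", "best_k"] = "nnls",
        loops: int = 30,
        inner_k: int = 5,
        k_best: int | None = None,
        n_trees: int = 500,
    ):
        self.base_specs = list(base_specs)
        self.combiner = combiner
        self.loops = loops
        self.inner_k = inner_k
        self.k_best = k_best
        self.n_trees = n_trees
        self.name = f"superlearner_{combiner}"

    def fit(self, clinical, omics, y, seed):
        self.model_ = superlearner_fit(
            clinical,
            omics,
            y,
            base_specs=self.base_specs,
            combiner=self.combiner,
            loops=self.loops,
            inner_k=self.inner_k,
            k_best=self.k_best,
            n_trees=self.n_trees,
            seed=seed,
        )
        self.cutoff_ = self.model_.tuned_cutoff
        return self

    def predict_scores(self, clinical, omics):
        return self.model_.predict(clinical, omics)
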