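"""Random-forest base models with out-of-bag (OOB) vote fractions.

Every sample is out of the bag for roughly ``e⁻¹`` of the trees; the
fraction of those trees voting for the positive class is an internally
cross-validated prediction for that training sample.  These per-sample OOB
positive-vote fractions are the raw material of hybrid integration: a whole
omics layer is compressed into one such column.  The decision cutoff on the
vote fraction is tuned to maximise the Matthews correlation coefficient on
the OOB predictions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn import config_context
from sklearn.ensemble import RandomForestClassifier

from .metrics import mcc_from_labels
from .tables import FeatureTable

__all__ = ["ForestModel", "train_forest", "tune_vote_cutoff", "predict_positive_fraction"]

DEFAULT_N_TREES = 500


@dataclass
class ForestModel:
    """A fitted forest plus its OOB vote bookkeeping and tuned cutoff."""

    estimator: RandomForestClassifier
    n_trees: int
    feature_names: list[str]
    oob_positive_fraction: np.ndarray  # per training sample, in [0, 1]
    oob_coverage: np.ndarray  # number of trees for which the sample was OOB
    inbag_positive_fraction: np.ndarray  # leakage diagnostic / negative control only
    seed: int
    tuned_cutoff: float = 0.5
    tuned_mcc: float = field(default=np.nan)

    def tune_cutoff(self, y) -> "ForestModel":
        self.tuned_cutoff, self.tuned_mcc = tune_vote_cutoff(
            self.oob_positive_fraction, np.asarray(y)
        )
        return self


def train_forest(
    X: FeatureTable,
    y,
    n_trees: int = DEFAULT_N_TREES,
    seed: int = 0,
    max_features: str | float = "sqrt",
) -> ForestModel:
    """Train a bagged forest and populate per-sample OOB vote fractions.

    Votes are hard per-tree class votes (not averaged probabilities).  A
    sample never out of the bag (possible at very small ``n_trees``) gets
    an OOB fraction of 0.5 and a warning.
    """
    y = np.asarray(y)
    M = X.values()
    if np.isnan(M).any():
        raise ValueError("training data contains missing values; impute first")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("single-class decision vector; cannot train a classifier")
    if counts.min() < 2:
        raise ValueError("need at least 2 samples per class")
    clf = RandomForestClassifier(
        n_estimators=n_trees,
        max_features=max_features,
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )
    with config_context(assume_finite=True):
        clf.fit(M, y)

    n = M.shape[0]
    pos_idx = int(np.flatnonzero(clf.classes_ == 1)[0])
    oob_votes = np.zeros(n)
    oob_cov = np.zeros(n, dtype=int)
    inbag_votes = np.zeros(n)
    inbag_cov = np.zeros(n, dtype=int)
    M32 = np.ascontiguousarray(M, dtype=np.float32)
    for tree, inbag in zip(clf.estimators_, clf.estimators_samples_):
        counts_inbag = np.bincount(inbag, minlength=n)
        oob_mask = counts_inbag == 0
        # raw per-tree hard votes; tree_.predict skips per-call validation
        pred = tree.tree_.predict(M32).reshape(n, -1).argmax(axis=1) == pos_idx
        oob_votes[oob_mask] += pred[oob_mask]
        oob_cov[oob_mask] += 1
        inbag_votes[~oob_mask] += pred[~oob_mask]
        inbag_cov[~oob_mask] += 1

    uncovered = oob_cov == 0
    if uncovered.any():
        warnings.warn(
            f"{int(uncovered.sum())} samples never OOB at n_trees={n_trees}; "
            "their OOB fraction is imputed as 0.5",
            stacklevel=2,
        )
    oob_frac = np.where(uncovered, 0.5, oob_votes / np.maximum(oob_cov, 1))
    inbag_frac = np.where(inbag_cov == 0, 0.5, inbag_votes / np.maximum(inbag_cov, 1))

    model = ForestModel(
        estimator=clf,
        n_trees=n_trees,
        feature_names=X.feature_names,
        oob_positive_fraction=oob_frac,
        oob_coverage=oob_cov,
        inbag_positive_fraction=inbag_frac,
        seed=seed,
    )
    return model.tune_cutoff(y)


def tune_vote_cutoff(scores, y) -> tuple[float, float]:
    """Cutoff on the vote fraction maximising MCC of the induced labels.

    The grid is every midpoint between consecutive distinct sorted scores,
    plus 0.5.  Ties in MCC are broken toward the cutoff closest to 0.5
    (then toward the smaller cutoff).  Constant scores return (0.5, MCC of
    the majority assignment).
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    if np.any((scores < 0) | (scores > 1)):
        raise ValueError("scores must lie in [0, 1]")
    distinct = np.unique(scores)
    if distinct.size == 1:
        return 0.5, mcc_from_labels((scores > 0.5).astype(int), y)
    grid = np.concatenate([(distinct[:-1] + distinct[1:]) / 2.0, [0.5]])
    best = None
    for cut in grid:
        m = mcc_from_labels((scores > cut).astype(int), y)
        key = (-m, abs(cut - 0.5), cut)
        if best is None or key < best[0]:
            best = (key, cut, m)
    return float(best[1]), float(best[2])


def predict_positive_fraction(model: ForestModel, X_new: FeatureTable) -> np.ndarray:
    """Fraction of trees voting positive for each new sample."""
    missing = [f for f in model.feature_names if f not in X_new.data.columns]
    if missing:
        raise KeyError(f"missing model features: {missing}")
    M = np.ascontiguousarray(
        X_new.data.loc[:, model.feature_names].to_numpy(dtype=np.float32)
    )
    clf = model.estimator
    pos_idx = int(np.flatnonzero(clf.classes_ == 1)[0])
    votes = np.zeros(M.shape[0])
    for tree in clf.estimators_:
        votes += tree.tree_.predict(M).reshape(M.shape[0], -1).argmax(axis=1) == pos_idx
    return votes / model.n_trees
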