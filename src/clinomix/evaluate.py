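"""Repeated stratified k-fold cross-validation and paired strategy comparison.

The entire pipeline — feature selection, base-model training, integration,
cutoff tuning — runs inside every training fold; held-out folds only ever
see fitted models.  (The one documented exception is the all-relevant
clinical selection, which is fixed once upstream.)  Strategies are compared
by a paired one-sided t-test on per-repeat mean AUC, together with the
count of repeats won.
"""

from __future__ import annotations

from abc import ABC, abstractmethod
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold, KFold

from .metrics import accuracy, auc, mcc_from_labels
from .tables import FeatureTable

__all__ = ["CVConfig", "MetricsRecord", "ComparisonSummary", "Strategy", "repeated_cv", "compare_strategies"]


@dataclass(frozen=True)
class CVConfig:
    r: int = 30
    k: int = 5
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.r < 1:
            raise ValueError("r must be >= 1")
        if self.k < 2:
            raise ValueError("k must be >= 2")


class MetricsRecord(NamedTuple):
    strategy: str
    repeat: int
    fold: int
    acc: float
    auc: float
    mcc: float


@dataclass
class ComparisonSummary:
    strategy_a: str
    strategy_b: str
    mean_auc_a: float
    mean_auc_b: float
    repeat_differences: np.ndarray  # per-repeat mean AUC(A) − mean AUC(B)
    t_statistic: float
    p_value: float  # one-sided, alternative: A > B
    wins: int  # repeats with mean AUC(A) strictly above B's
    n_repeats: int


class Strategy(ABC):
    """A trainable/predictable pipeline evaluated by :func:`repeated_cv`.

    ``fit`` receives only the training split; ``predict_scores`` returns a
    positive-class score per sample of the given tables.  ``cutoff_`` is
    the fold's tuned decision threshold on those scores.
    """

    name: str = "strategy"
    cutoff_: float = 0.5

    @abstractmethod
    def fit(self, clinical: FeatureTable, omics: dict[str, FeatureTable], y, seed: int) -> "Strategy":
        ...

    @abstractmethod
    def predict_scores(self, clinical: FeatureTable, omics: dict[str, FeatureTable]) -> np.ndarray:
        ...


def repeated_cv(
    clinical: FeatureTable,
    omics: dict[str, FeatureTable],
    y: pd.Series,
    strategy: Strategy,
    config: CVConfig = CVConfig(),
) -> pd.DataFrame:
    """Run ``r`` repeats of ``k``-fold CV; returns a tidy frame of r·k records.

    Each repeat draws a fresh (stratified) partition from the config seed;
    metrics on the held-out fold use raw scores for AUC and the fold's
    tuned cutoff for ACC/MCC.
    """
    y = pd.Series(np.asarray(y), index=clinical.sample_ids)
    class_counts = y.value_counts()
    if config.stratified and config.k > class_counts.min():
        raise ValueError(
            f"k={config.k} exceeds minority class count {class_counts.min()}"
        )
    root = np.random.default_rng(config.seed)
    repeat_seeds = root.integers(2**31 - 1, size=config.r)
    fit_seeds = root.integers(2**31 - 1, size=(config.r, config.k))

    ids = clinical.sample_ids
    records: list[MetricsRecord] = []
    for rep in range(config.r):
        splitter_cls = StratifiedKFold if config.stratified else KFold
        splitter = splitter_cls(n_splits=config.k, shuffle=True, random_state=int(repeat_seeds[rep]))
        for fold, (tr, te) in enumerate(splitter.split(np.zeros(len(ids)), y.to_numpy())):
            y_tr, y_te = y.iloc[tr], y.iloc[te]
            if y_tr.nunique() < 2 or y_te.nunique() < 2:
                raise ValueError(
                    "a fold contains a single class; use stratified folds or larger data"
                )
            clin_tr = clinical.restrict(ids[tr])
            clin_te = clinical.restrict(ids[te])
            om_tr = {k: t.restrict(ids[tr]) for k, t in omics.items()}
            om_te = {k: t.restrict(ids[te]) for k, t in omics.items()}
            strategy.fit(clin_tr, om_tr, y_tr, seed=int(fit_seeds[rep, fold]))
            scores = np.asarray(strategy.predict_scores(clin_te, om_te), dtype=float)
            pred = (scores > strategy.cutoff_).astype(int)
            records.append(
                MetricsRecord(
                    strategy=strategy.name,
                    repeat=rep,
                    fold=fold,
                    acc=accuracy(pred, y_te),
                    auc=auc(scores, y_te),
                    mcc=mcc_from_labels(pred, y_te),
                )
            )
    return pd.DataFrame(records)


def per_repeat_mean(records: pd.DataFrame, metric: str = "auc") -> pd.Series:
    return records.groupby("repeat")[metric].mean()


def compare_strategies(
    records_a: pd.DataFrame, records_b: pd.DataFrame, metric: str = "auc"
) -> ComparisonSummary:
    """Paired one-sided t-test (A > B) on per-repeat mean AUC, plus win count.

    Zero-variance differences are handled by convention: identical records
    give t = 0 and p = 0.5; a constant positive (negative) shift gives
    p → 0 (→ 1).
    """
    a = per_repeat_mean(records_a, metric)
    b = per_repeat_mean(records_b, metric)
    if len(a) != len(b) or not (
        records_a.groupby("repeat").size().equals(records_b.groupby("repeat").size())
    ):
        raise ValueError("records do not share the same (repeat, fold) structure")
    d = (a - b).to_numpy()
    r = len(d)
    wins = int((d > 0).sum())
    if np.allclose(d.std(ddof=1) if r > 1 else 0.0, 0.0):
        m = d.mean()
        if m > 0:
            t, p = np.inf, 0.0
        elif m < 0:
            t, p = -np.inf, 1.0
        else:
            t, p = 0.0, 0.5
    else:
        t, p = stats.ttest_rel(a, b, alternative="greater")
        t, p = float(t), float(p)
    name_a = records_a["strategy"].iloc[0] if len(records_a) else "A"
    name_b = records_b["strategy"].iloc[0] if len(records_b) else "B"
    return ComparisonSummary(
        strategy_a=name_a,
        strategy_b=name_b,
        mean_auc_a=float(a.mean()),
        mean_auc_b=float(b.mean()),
        repeat_differences=d,
        t_statistic=t,
        p_value=p,
        wins=wins,
        n_repeats=r,
    )
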