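"""Feature ranking, multiple-testing correction and redundancy removal.

Molecular features are ranked by a filter statistic — the Mann–Whitney
U-test or an entropy-based multidimensional filter (MDFS) in one or two
dimensions — and the resulting p-values are corrected with the sequential
goodness-of-fit (SGoF) procedure, which compares the observed count of
small p-values to its binomial expectation and is optimised for power
rather than strict false-discovery control.  The significant features are
then pruned greedily so that no two kept features exceed a Spearman
correlation threshold, and the survivors are capped at the top ``m``.

Clinical tables, which mix numeric, ordinal and categorical variables, use
an all-relevant shadow-feature selector instead (Boruta-style): permuted
copies of the features compete with the originals for random-forest
importance, and a binomial test over iterations confirms or rejects each
feature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .tables import FeatureTable

__all__ = [
    "FeatureRanking",
    "SelectionConfig",
    "SelectedFeatureSet",
    "u_test_rank",
    "mdfs_rank",
    "sgof_select",
    "greedy_redundancy_filter",
    "select_features",
    "shadow_select_clinical",
]

_LN2 = np.log(2.0)


@dataclass
class FeatureRanking:
    """Features ordered by ascending p-value (ties: descending score, then name)."""

    features: list[str]
    p_values: np.ndarray  # aligned to `features`, in [0, 1]
    scores: np.ndarray  # U statistic, or information gain in bits
    method: Literal["utest", "mdfs1d", "mdfs2d"]

    def __post_init__(self) -> None:
        self.p_values = np.asarray(self.p_values, dtype=float)
        self.scores = np.asarray(self.scores, dtype=float)
        if np.any((self.p_values < 0) | (self.p_values > 1)):
            raise ValueError("p-values outside [0, 1]")

    @classmethod
    def from_unsorted(cls, names, p_values, scores, method) -> "FeatureRanking":
        order = sorted(
            range(len(names)), key=lambda i: (p_values[i], -scores[i], names[i])
        )
        return cls(
            features=[names[i] for i in order],
            p_values=np.asarray(p_values, float)[order],
            scores=np.asarray(scores, float)[order],
            method=method,
        )


@dataclass(frozen=True)
class SelectionConfig:
    method: Literal["utest", "mdfs1d", "mdfs2d"] = "utest"
    sgof_gamma: float = 0.05
    sgof_alpha: float = 0.05
    rho_max: float = 0.7
    m_cap: int = 100
    # MDFS discretization: continuous features are cut into n_bins bins at
    # random quantile split points; the best information gain over
    # n_discretizations draws is kept.
    n_bins: int = 2
    n_discretizations: int = 30
    disc_range: float = 0.25  # splits drawn from quantiles in (range, 1-range)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.rho_max <= 1.0:
            raise ValueError("rho_max must be in (0, 1]")
        if self.m_cap < 1:
            raise ValueError("m_cap must be >= 1")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")


@dataclass
class SelectedFeatureSet:
    """Ordered kept features plus the counts of each selection stage."""

    features: list[str]
    p_values: dict[str, float]
    scores: dict[str, float]
    n_significant_after_sgof: int
    n_after_redundancy: int
    n_final: int
    method: str
    empty_warning: bool = False
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.features)


# ---------------------------------------------------------------------------
# Rankings


def _split_classes(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("decision vector must be binary 0/1")
    n0, n1 = int((y == 0).sum()), int((y == 1).sum())
    if n0 < 1 or n1 < 1:
        raise ValueError("both decision classes must be non-empty")
    return X[y == 0], X[y == 1]


def u_test_rank(X: FeatureTable, y) -> FeatureRanking:
    """Rank features by the two-sided Mann–Whitney U-test.

    The exact null distribution is used when n ≤ 20 and the feature has no
    ties; otherwise the normal approximation with tie correction.  A feature
    constant across all samples carries no information and gets p = 1.
    """
    if X.n_features < 1:
        raise ValueError("need at least one feature")
    y = np.asarray(y)
    M = X.values()
    X0, X1 = _split_classes(M, y)
    n = M.shape[0]
    p_values = np.empty(X.n_features)
    scores = np.empty(X.n_features)
    if n > 20:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # constant columns handled below
            res = stats.mannwhitneyu(X0, X1, axis=0, method="asymptotic")
        p_values[:] = res.pvalue
        scores[:] = res.statistic
    else:
        for j in range(X.n_features):
            has_ties = len(np.unique(M[:, j])) < n
            method = "asymptotic" if has_ties else "exact"
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = stats.mannwhitneyu(X0[:, j], X1[:, j], method=method)
            p_values[j], scores[j] = res.pvalue, res.statistic
    constant = np.array([len(np.unique(M[:, j])) == 1 for j in range(X.n_features)])
    p_values[constant] = 1.0
    p_values = np.clip(np.nan_to_num(p_values, nan=1.0), 0.0, 1.0)
    return FeatureRanking.from_unsorted(X.feature_names, p_values, scores, "utest")


def _entropy_bits(counts: np.ndarray) -> float:
    """Shannon entropy (bits) of a count vector."""
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def _discretize(
    M: np.ndarray, config: SelectionConfig, rng: np.random.Generator
):
    """Yield random discretizations of each column into ``n_bins`` codes.

    A column whose number of distinct values does not exceed ``n_bins`` is
    used as-is (deterministic, identical across draws); continuous columns
    are cut at ``n_bins - 1`` random quantile split points per draw, the
    quantiles drawn uniformly from (disc_range, 1 − disc_range).
    """
    n, p = M.shape
    lo, hi = config.disc_range, 1.0 - config.disc_range
    n_uniq = np.array([len(np.unique(M[:, j])) for j in range(p)])
    discrete = n_uniq <= config.n_bins
    fixed = np.empty((n, p), dtype=np.int64)
    for j in np.flatnonzero(discrete):
        fixed[:, j] = np.searchsorted(np.unique(M[:, j]), M[:, j])
    Msort = np.sort(M, axis=0)
    cont = np.flatnonzero(~discrete)
    n_draws = 1 if cont.size == 0 else config.n_discretizations
    for _ in range(n_draws):
        D = fixed.copy()
        if cont.size:
            qs = np.sort(lo + (hi - lo) * rng.random((config.n_bins - 1, cont.size)), axis=0)
            pos = qs * (n - 1)
            base = np.floor(pos).astype(int)
            frac = pos - base
            # per-column linear-interpolation quantiles of the sorted data
            edges = (
                Msort[base, cont[None, :]] * (1 - frac)
                + Msort[np.minimum(base + 1, n - 1), cont[None, :]] * frac
            )  # (n_bins-1, n_cont)
            codes = (M[:, cont][None, :, :] > edges[:, None, :]).sum(axis=0)
            D[:, cont] = codes
        yield D


def _cond_entropy_bits_vec(y: np.ndarray, D: np.ndarray, n_cells: int) -> np.ndarray:
    """H(Y | cell) in bits, vectorised across the columns of code matrix D."""
    n, p = D.shape
    h = np.zeros(p)
    offset = D + n_cells * np.arange(p)[None, :]
    pos = np.bincount(offset[y == 1].ravel(), minlength=n_cells * p).reshape(p, n_cells)
    tot = np.bincount(offset.ravel(), minlength=n_cells * p).reshape(p, n_cells)
    neg = tot - pos
    f_pos = pos / np.maximum(tot, 1)
    f_neg = neg / np.maximum(tot, 1)
    h_cell = np.zeros_like(f_pos)
    m = pos > 0
    h_cell[m] -= f_pos[m] * np.log2(f_pos[m])
    m = neg > 0
    h_cell[m] -= f_neg[m] * np.log2(f_neg[m])
    return (tot / n * h_cell).sum(axis=1)


def mdfs_rank(X: FeatureTable, y, config: SelectionConfig) -> FeatureRanking:
    """Entropy-based multidimensional filter ranking (MDFS), D = 1 or 2.

    For D = 1 the score of feature ``f`` is the information gain
    ``IG(f) = H(Y) − H(Y | disc(f))`` maximised over random discretizations.
    For D = 2 it is the conditional gain attributed to ``f`` within its best
    pair, ``max_g [H(Y | disc(g)) − H(Y | disc(f), disc(g))]`` — which
    detects interactions (e.g. XOR) invisible to one-dimensional filters.

    P-values come from the asymptotic chi-square distribution of the
    likelihood-ratio statistic ``2·N·IG`` (in nats), with
    ``df = n_bins − 1`` for D = 1 and ``df = (n_bins − 1)·n_bins`` for
    D = 2 (one set of bin contrasts per conditioning cell).  Scores are
    reported in bits.
    """
    dim = {"mdfs1d": 1, "mdfs2d": 2}.get(config.method)
    if dim is None:
        raise ValueError(f"mdfs_rank requires method mdfs1d or mdfs2d, got {config.method}")
    y = np.asarray(y)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("decision vector must be binary 0/1")
    M = X.values()
    n, p = M.shape
    if dim == 2 and p < 2:
        raise ValueError("two-dimensional MDFS needs at least 2 features")
    rng = np.random.default_rng(config.seed)
    h_y = _entropy_bits(np.array([(y == 0).sum(), (y == 1).sum()]))
    b = config.n_bins

    best = np.zeros(p)
    if dim == 1:
        for D in _discretize(M, config, rng):
            ig = h_y - _cond_entropy_bits_vec(y, D, b)
            np.maximum(best, ig, out=best)
        df = b - 1
    else:
        for D in _discretize(M, config, rng):
            h_single = _cond_entropy_bits_vec(y, D, b)
            for j in range(p):
                others = np.flatnonzero(np.arange(p) != j)
                cells = D[:, [j]] * b + D[:, others]
                h_pair = _cond_entropy_bits_vec(y, cells, b * b)
                ig = (h_single[others] - h_pair).max()
                if ig > best[j]:
                    best[j] = ig
        df = (b - 1) * b

    stat = 2.0 * n * best * _LN2  # bits -> nats
    p_values = stats.chi2.sf(stat, df=df)
    return FeatureRanking.from_unsorted(X.feature_names, p_values, best, config.method)


# ---------------------------------------------------------------------------
# SGoF and redundancy


def sgof_select(p_values, gamma: float = 0.05, alpha: float = 0.05) -> int:
    """Sequential goodness-of-fit: number of smallest p-values declared significant.

    Let ``F`` be the count of p-values at or below ``gamma``.  While a
    one-sided binomial test of ``F`` successes in ``n`` trials at success
    rate ``gamma`` is significant at level ``alpha``, the smallest
    undeclared p-value is declared significant and ``F`` is decremented.
    Returns the number of declarations ``R`` (0 ≤ R ≤ #{p ≤ gamma}).
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]")
    n = p.size
    F = int((p <= gamma).sum())
    R = 0
    while F > 0 and stats.binom.sf(F - 1, n, gamma) <= alpha:
        R += 1
        F -= 1
    return R


def _spearman_ranks(M: np.ndarray) -> np.ndarray:
    """Column-wise average ranks, centred — Spearman ρ is then a cosine."""
    R = np.apply_along_axis(stats.rankdata, 0, M)
    R = R - R.mean(axis=0, keepdims=True)
    norms = np.sqrt((R**2).sum(axis=0))
    norms[norms == 0] = 1.0  # constant column: ρ defined as 0 against anything
    return R / norms


def greedy_redundancy_filter(
    ranking: FeatureRanking,
    X: FeatureTable,
    rho_max: float = 0.7,
    n_keep_max: int | None = None,
) -> SelectedFeatureSet:
    """Walk the ranking, keeping a feature only if its |Spearman ρ| with every
    already-kept feature is below ``rho_max``; stop once ``n_keep_max`` kept."""
    if rho_max <= 0:
        raise ValueError("rho_max must be positive")
    missing = [f for f in ranking.features if f not in X.data.columns]
    if missing:
        raise KeyError(f"ranking features absent from table: {missing[:5]}")
    if n_keep_max is None:
        n_keep_max = len(ranking.features)
    M = X.data.loc[:, ranking.features].to_numpy(dtype=float)
    R = _spearman_ranks(M)
    kept_idx: list[int] = []
    for j in range(len(ranking.features)):
        if kept_idx:
            rho = R[:, kept_idx].T @ R[:, j]
            if np.any(np.abs(rho) >= rho_max):
                continue
        kept_idx.append(j)
        if len(kept_idx) >= n_keep_max:
            break
    kept = [ranking.features[j] for j in kept_idx]
    return SelectedFeatureSet(
        features=kept,
        p_values={f: float(ranking.p_values[ranking.features.index(f)]) for f in kept},
        scores={f: float(ranking.scores[ranking.features.index(f)]) for f in kept},
        n_significant_after_sgof=len(ranking.features),
        n_after_redundancy=len(kept),
        n_final=len(kept),
        method=ranking.method,
    )


def select_features(X: FeatureTable, y, config: SelectionConfig) -> SelectedFeatureSet:
    """Full molecular selection: rank → SGoF → greedy redundancy → top-m cap.

    Zero significant features is not an error: an empty set is returned with
    ``empty_warning`` set so that callers can skip the layer.
    """
    if config.method == "utest":
        ranking = u_test_rank(X, y)
    else:
        ranking = mdfs_rank(X, y, config)
    n_sig = sgof_select(ranking.p_values, config.sgof_gamma, config.sgof_alpha)
    if n_sig == 0:
        warnings.warn(f"no significant features in {X.modality} after SGoF", stacklevel=2)
        return SelectedFeatureSet(
            features=[], p_values={}, scores={}, n_significant_after_sgof=0,
            n_after_redundancy=0, n_final=0, method=config.method, empty_warning=True,
        )
    sig = FeatureRanking(
        features=ranking.features[:n_sig],
        p_values=ranking.p_values[:n_sig],
        scores=ranking.scores[:n_sig],
        method=ranking.method,
    )
    selected = greedy_redundancy_filter(sig, X, config.rho_max, n_keep_max=config.m_cap)
    selected.n_significant_after_sgof = n_sig
    selected.n_final = min(len(selected.features), config.m_cap)
    selected.features = selected.features[: selected.n_final]
    selected.provenance = {"config": config, "modality": X.modality}
    return selected


# ---------------------------------------------------------------------------
# All-relevant clinical selection (shadow features)


def shadow_select_clinical(
    X: FeatureTable,
    y,
    n_iterations: int = 50,
    alpha: float = 0.01,
    seed: int = 0,
    n_trees: int = 200,
) -> tuple[list[str], pd.DataFrame]:
    """Boruta-style all-relevant selection for clinical features.

    At each iteration every feature gets a shuffled shadow copy, a random
    forest is trained on the augmented table, and a feature scores a *hit*
    when its importance exceeds the maximum shadow importance.  Features
    are confirmed (or rejected) by two-sided binomial tests at level
    ``alpha`` with Bonferroni correction across features.  Returns the
    confirmed features ordered by mean importance, and a per-feature
    summary frame (hits, mean importance, status).

    Intended to be run once on the full data set: clinical variables are
    few and the relevant/irrelevant border is sharp, but this does
    introduce a small optimistic bias for a clinical-only baseline
    evaluated by cross-validation on the same data.
    """
    from sklearn.ensemble import RandomForestClassifier

    if X.n_features < 2:
        raise ValueError("need at least 2 features")
    if n_iterations < 5:
        raise ValueError("n_iterations must be >= 5")
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    M = X.values()
    n, p = M.shape
    names = X.feature_names
    hits = np.zeros(p, dtype=int)
    imp_sum = np.zeros(p)
    status = np.array(["tentative"] * p, dtype=object)

    for it in range(1, n_iterations + 1):
        shadows = M.copy()
        for j in range(p):
            shadows[:, j] = shadows[rng.permutation(n), j]
        aug = np.hstack([M, shadows])
        clf = RandomForestClassifier(
            n_estimators=n_trees,
            max_features="sqrt",
            random_state=int(rng.integers(2**31 - 1)),
            n_jobs=1,
        ).fit(aug, y)
        imp = clf.feature_importances_
        shadow_max = imp[p:].max()
        hits += imp[:p] > shadow_max
        imp_sum += imp[:p]
        # binomial confirm/reject with Bonferroni across the p features
        undecided = status == "tentative"
        if undecided.any():
            p_hi = stats.binom.sf(hits[undecided] - 1, it, 0.5) * p
            p_lo = stats.binom.cdf(hits[undecided], it, 0.5) * p
            idx = np.flatnonzero(undecided)
            status[idx[p_hi < alpha]] = "confirmed"
            status[idx[p_lo < alpha]] = "rejected"

    mean_imp = imp_sum / n_iterations
    summary = pd.DataFrame(
        {"feature": names, "hits": hits, "mean_importance": mean_imp, "status": status}
    ).sort_values("mean_importance", ascending=False, ignore_index=True)
    confirmed = summary.loc[summary["status"] == "confirmed", "feature"].tolist()
    return confirmed, summary
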