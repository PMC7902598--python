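"""Independent brute-force oracles used to verify the implementation.

Each function here recomputes a quantity by exhaustive enumeration or a
direct textbook formula, deliberately sharing no code with the package.
"""

from __future__ import annotations

import itertools
import math
from functools import lru_cache

import numpy as np


# ---------------------------------------------------------------------------
# Mann-Whitney U-test by exhaustive enumeration of rank assignments


@lru_cache(maxsize=None)
def u_null_distribution(n1: int, n2: int) -> dict[int, int]:
    """Counts of each U value over all C(n1+n2, n1) rank assignments."""
    n = n1 + n2
    counts: dict[int, int] = {}
    for combo in itertools.combinations(range(n), n1):
        # U for sample 1 = sum of ranks of sample 1 minus its minimum
        u = sum(combo) - n1 * (n1 - 1) // 2
        counts[u] = counts.get(u, 0) + 1
    return counts


def u_test_pvalue_exact(x0, x1) -> float:
    """Two-sided exact Mann-Whitney p-value for tie-free samples."""
    x0, x1 = np.asarray(x0, float), np.asarray(x1, float)
    n1, n2 = len(x0), len(x1)
    u1 = sum(1 for a in x0 for b in x1 if a > b)
    dist = u_null_distribution(n1, n2)
    total = math.comb(n1 + n2, n1)
    u_hi = max(u1, n1 * n2 - u1)
    p = sum(c for u, c in dist.items() if u >= u_hi or u <= n1 * n2 - u_hi) / total
    return min(1.0, p)


# ---------------------------------------------------------------------------
# Confusion metrics


def mcc_formula(tp, tn, fp, fn) -> float:
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / denom


def auc_pairs(scores, y) -> float:
    """AUC by enumeration of all positive-negative pairs (ties count half)."""
    scores, y = np.asarray(scores, float), np.asarray(y)
    pos = scores[y == 1]
    neg = scores[y == 0]
    wins = sum(1.0 if a > b else (0.5 if a == b else 0.0) for a in pos for b in neg)
    return wins / (len(pos) * len(neg))


def best_cutoff_exhaustive(scores, y) -> tuple[float, float]:
    """Brute-force optimal MCC cutoff over all midpoints plus 0.5."""
    scores, y = np.asarray(scores, float), np.asarray(y)
    distinct = np.unique(scores)
    if distinct.size == 1:
        pred = (scores > 0.5).astype(int)
        tp = int(((pred == 1) & (y == 1)).sum()); tn = int(((pred == 0) & (y == 0)).sum())
        fp = int(((pred == 1) & (y == 0)).sum()); fn = int(((pred == 0) & (y == 1)).sum())
        return 0.5, mcc_formula(tp, tn, fp, fn)
    grid = list((distinct[:-1] + distinct[1:]) / 2) + [0.5]
    best = None
    for cut in grid:
        pred = (scores > cut).astype(int)
        tp = int(((pred == 1) & (y == 1)).sum()); tn = int(((pred == 0) & (y == 0)).sum())
        fp = int(((pred == 1) & (y == 0)).sum()); fn = int(((pred == 0) & (y == 1)).sum())
        m = mcc_formula(tp, tn, fp, fn)
        key = (-m, abs(cut - 0.5), cut)
        if best is None or key < best[0]:
            best = (key, cut, m)
    return float(best[1]), float(best[2])


# ---------------------------------------------------------------------------
# SGoF by direct iteration with exact binomial tails


def binom_tail_ge(k: int, n: int, p: float) -> float:
    """P(X >= k) for X ~ Binomial(n, p), by direct summation."""
    return sum(math.comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(k, n + 1))


def sgof_oracle(pvalues, gamma: float = 0.05, alpha: float = 0.05) -> int:
    p = sorted(pvalues)
    n = len(p)
    F = sum(1 for v in p if v <= gamma)
    R = 0
    while F > 0 and binom_tail_ge(F, n, gamma) <= alpha:
        R += 1
        F -= 1
    return R


# ---------------------------------------------------------------------------
# Greedy redundancy removal by direct rule application


def spearman_rho(a, b) -> float:
    from scipy.stats import rankdata

    ra, rb = rankdata(a), rankdata(b)
    ra = ra - ra.mean(); rb = rb - rb.mean()
    na, nb = np.sqrt((ra**2).sum()), np.sqrt((rb**2).sum())
    if na == 0 or nb == 0:
        return 0.0
    return float((ra * rb).sum() / (na * nb))


def greedy_filter_oracle(ordered_names, columns: dict, rho_max: float, n_keep_max: int) -> list:
    kept = []
    for name in ordered_names:
        if all(abs(spearman_rho(columns[name], columns[k])) < rho_max for k in kept):
            kept.append(name)
        if len(kept) >= n_keep_max:
            break
    return kept


# ---------------------------------------------------------------------------
# Entropy / information gain on a contingency table


def entropy_bits(counts) -> float:
    counts = np.asarray(counts, float)
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


def info_gain_bits(x_codes, y) -> float:
    """Plug-in IG(Y; X) in bits from discrete codes."""
    x_codes, y = np.asarray(x_codes), np.asarray(y)
    n = len(y)
    h_y = entropy_bits(np.bincount(y))
    h_cond = 0.0
    for v in np.unique(x_codes):
        mask = x_codes == v
        h_cond += mask.mean() * entropy_bits(np.bincount(y[mask], minlength=2))
    return h_y - h_cond
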