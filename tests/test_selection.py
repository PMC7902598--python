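"""Feature ranking, SGoF, redundancy removal and the shadow selector."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from clinomix import (
    FeatureRanking,
    SelectionConfig,
    greedy_redundancy_filter,
    mdfs_rank,
    select_features,
    sgof_select,
    shadow_select_clinical,
    u_test_rank,
)
from conftest import make_table
import oracles


# ---------------------------------------------------------------------------
# U-test


def test_utest_exact_separated_samples():
    # class0 = (1,2,3), class1 = (4,5,6): U = 0, two-sided exact p = 2/20
    t = make_table(np.array([[1], [2], [3], [4], [5], [6]], dtype=float))
    r = u_test_rank(t, np.array([0, 0, 0, 1, 1, 1]))
    assert r.p_values[0] == pytest.approx(0.1, abs=1e-12)


def test_utest_exact_interleaved_p_one():
    t = make_table(np.array([[1], [4], [2], [3]], dtype=float))
    r = u_test_rank(t, np.array([0, 0, 1, 1]))
    assert r.p_values[0] == pytest.approx(1.0, abs=1e-12)
    assert r.scores[0] == 2  # U = n1*n2/2


def test_utest_constant_feature_p_one():
    t = make_table(np.column_stack([np.ones(10), np.arange(10.0)]))
    y = np.array([0] * 5 + [1] * 5)
    r = u_test_rank(t, y)
    assert r.p_values[list(r.features).index("f0")] == 1.0


def test_utest_matches_enumeration_oracle_small_n():
    """Exact p-values agree with exhaustive rank-assignment enumeration (<=1e-10)."""
    rng = np.random.default_rng(0)
    for trial in range(60):
        n1 = int(rng.integers(2, 8))
        n2 = int(rng.integers(2, 8))
        vals = rng.permutation(np.arange(1.0, n1 + n2 + 1))  # tie-free
        x0, x1 = vals[:n1], vals[n1:]
        t = make_table(np.concatenate([x0, x1])[:, None])
        y = np.array([0] * n1 + [1] * n2)
        p = u_test_rank(t, y).p_values[0]
        assert p == pytest.approx(oracles.u_test_pvalue_exact(x0, x1), abs=1e-10)


def test_utest_requires_both_classes():
    t = make_table(np.arange(6.0)[:, None])
    with pytest.raises(ValueError):
        u_test_rank(t, np.zeros(6, dtype=int))


# ---------------------------------------------------------------------------
# MDFS


def test_mdfs1d_information_gain_on_binary_contingency():
    """Joint counts (40,10;10,40): IG = 1 - H2(0.8) = 0.2781 bits."""
    f = np.array([0] * 40 + [1] * 10 + [0] * 10 + [1] * 40, dtype=float)
    y = np.array([0] * 50 + [1] * 50)
    t = make_table(np.column_stack([f, f]))
    r = mdfs_rank(t, y, SelectionConfig(method="mdfs1d"))
    h2 = -(0.8 * np.log2(0.8) + 0.2 * np.log2(0.2))
    assert r.scores[0] == pytest.approx(1.0 - h2, abs=1e-9)
    assert r.scores[0] == pytest.approx(0.2781, abs=1e-4)


def test_mdfs1d_equals_plugin_entropy_oracle_on_discrete_features():
    rng = np.random.default_rng(1)
    X = rng.integers(0, 2, size=(200, 6)).astype(float)
    y = ((X[:, 0] + rng.random(200) * 0.8) > 0.9).astype(int)
    t = make_table(X)
    r = mdfs_rank(t, y, SelectionConfig(method="mdfs1d"))
    for j, name in enumerate(t.feature_names):
        expected = oracles.info_gain_bits(X[:, j].astype(int), y)
        got = r.scores[list(r.features).index(name)]
        assert got == pytest.approx(expected, abs=1e-9)


def test_mdfs_xor_detected_only_in_two_dimensions():
    rng = np.random.default_rng(2)
    n = 2000
    f1 = rng.integers(0, 2, n)
    f2 = rng.integers(0, 2, n)
    y = f1 ^ f2
    X = np.column_stack([f1, f2, rng.standard_normal(n)]).astype(float)
    t = make_table(X, names=["f1", "f2", "noise"])
    r1 = mdfs_rank(t, y, SelectionConfig(method="mdfs1d"))
    r2 = mdfs_rank(t, y, SelectionConfig(method="mdfs2d"))
    s1 = {f: s for f, s in zip(r1.features, r1.scores)}
    s2 = {f: s for f, s in zip(r2.features, r2.scores)}
    assert s1["f1"] < 0.01 and s1["f2"] < 0.01
    assert s2["f1"] > 0.9 and s2["f2"] > 0.9


def test_mdfs1d_null_scores_near_zero_pvalues_spread():
    rng = np.random.default_rng(3)
    X = rng.standard_normal((600, 40))
    y = rng.integers(0, 2, 600)
    r = mdfs_rank(make_table(X), y, SelectionConfig(method="mdfs1d", n_discretizations=5))
    assert r.scores.max() < 0.03  # bits
    assert r.p_values.min() > 1e-4  # no spurious certainty under the null


def test_mdfs2d_requires_two_features():
    t = make_table(np.arange(10.0)[:, None])
    with pytest.raises(ValueError):
        mdfs_rank(t, np.array([0, 1] * 5), SelectionConfig(method="mdfs2d"))


# ---------------------------------------------------------------------------
# SGoF


def test_sgof_no_small_pvalues_yields_zero():
    assert sgof_select([0.9] * 100) == 0


def test_sgof_matches_binomial_oracle():
    cases = [
        [0.001] * 20 + [0.5] * 80,
        [0.04] * 10,
        [0.01] * 5 + [0.2] * 95,
        list(np.linspace(0.001, 1.0, 50)),
    ]
    for pvals in cases:
        expected = oracles.sgof_oracle(pvals, 0.05, 0.05)
        assert sgof_select(pvals, 0.05, 0.05) == expected
    assert sgof_select([0.001] * 20 + [0.5] * 80) > 0


def test_sgof_randomized_instances_match_oracle():
    rng = np.random.default_rng(4)
    for _ in range(200):
        n = int(rng.integers(1, 60))
        pvals = rng.random(n) ** float(rng.choice([1, 2, 4]))
        got = sgof_select(pvals, 0.05, 0.05)
        assert got == oracles.sgof_oracle(pvals, 0.05, 0.05)
        assert 0 <= got <= (np.asarray(pvals) <= 0.05).sum()


def test_sgof_null_false_positive_fraction_moderate():
    """Under uniform p-values the declared fraction stays below ~10% on average."""
    rng = np.random.default_rng(5)
    fracs = [sgof_select(rng.random(500), 0.05, 0.05) / 500 for _ in range(50)]
    assert np.mean(fracs) < 0.10


def test_sgof_rejects_empty_and_bad_input():
    with pytest.raises(ValueError):
        sgof_select([])
    with pytest.raises(ValueError):
        sgof_select([0.5, 1.2])


# ---------------------------------------------------------------------------
# Redundancy removal


def _ranking(names):
    return FeatureRanking(
        features=list(names),
        p_values=np.linspace(0.001, 0.01, len(names)),
        scores=np.arange(len(names), 0, -1, dtype=float),
        method="utest",
    )


def test_greedy_filter_blocks_correlated_lower_ranked():
    rng = np.random.default_rng(6)
    f1 = rng.standard_normal(200)
    f2 = 0.95 * f1 + 0.05 * rng.standard_normal(200)  # |rho| ~ 0.95 with f1
    f3 = rng.standard_normal(200) + 0.3 * f1  # weak with f1, weak with f2
    t = make_table(np.column_stack([f1, f2, f3]), names=["f1", "f2", "f3"])
    kept = greedy_redundancy_filter(_ranking(["f1", "f2", "f3"]), t, rho_max=0.7)
    assert kept.features == ["f1", "f3"]


def test_greedy_filter_duplicate_always_removed():
    rng = np.random.default_rng(7)
    f1 = rng.standard_normal(100)
    t = make_table(np.column_stack([f1, f1.copy()]), names=["a", "a_dup"])
    kept = greedy_redundancy_filter(_ranking(["a", "a_dup"]), t, rho_max=0.7)
    assert kept.features == ["a"]


def test_greedy_filter_independent_features_all_kept_up_to_cap():
    rng = np.random.default_rng(8)
    t = make_table(rng.standard_normal((300, 10)))
    names = t.feature_names
    kept = greedy_redundancy_filter(_ranking(names), t, rho_max=0.7, n_keep_max=6)
    assert kept.features == names[:6]


def test_greedy_filter_matches_direct_rule_oracle():
    rng = np.random.default_rng(9)
    for _ in range(30):
        n, p = 60, 8
        base = rng.standard_normal((n, 3))
        mix = rng.random((3, p))
        X = base @ mix + 0.6 * rng.standard_normal((n, p))
        t = make_table(X)
        names = t.feature_names
        kept = greedy_redundancy_filter(_ranking(names), t, rho_max=0.6, n_keep_max=p)
        cols = {nm: X[:, j] for j, nm in enumerate(names)}
        assert kept.features == oracles.greedy_filter_oracle(names, cols, 0.6, p)


def test_greedy_filter_invariant_to_tail_shuffle():
    rng = np.random.default_rng(10)
    X = rng.standard_normal((100, 12))
    t = make_table(X)
    names = t.feature_names
    kept = greedy_redundancy_filter(_ranking(names), t, rho_max=0.7, n_keep_max=4).features
    # shuffling features ranked after the 4th kept one leaves the result unchanged
    tail = names[6:]
    shuffled = names[:6] + [tail[i] for i in rng.permutation(len(tail))]
    kept2 = greedy_redundancy_filter(_ranking(shuffled), t, rho_max=0.7, n_keep_max=4).features
    assert kept == kept2


# ---------------------------------------------------------------------------
# Composed selection


def test_select_features_null_rarely_selects(null_cohort):
    clinical, omics, y, _ = null_cohort
    sel = select_features(omics["GE"], y, SelectionConfig(method="utest"))
    assert sel.n_final < 20  # far below the m=100 cap on a null layer


def test_select_features_composition_matches_staged_oracle(small_signal_cohort):
    clinical, omics, y, _ = small_signal_cohort
    cfg = SelectionConfig(method="utest", m_cap=30)
    sel = select_features(omics["GE"], y, cfg)
    ranking = u_test_rank(omics["GE"], y)
    n_sig = oracles.sgof_oracle(ranking.p_values, 0.05, 0.05)
    assert sel.n_significant_after_sgof == n_sig
    cols = {nm: omics["GE"].data[nm].to_numpy() for nm in ranking.features[:n_sig]}
    expected = oracles.greedy_filter_oracle(ranking.features[:n_sig], cols, 0.7, 30)
    assert sel.features == expected
    assert sel.n_final <= 30
    assert sel.n_final <= sel.n_after_redundancy <= sel.n_significant_after_sgof


def test_select_features_m_cap_enforced(small_signal_cohort):
    clinical, omics, y, _ = small_signal_cohort
    sel = select_features(omics["GE"], y, SelectionConfig(method="mdfs1d", m_cap=5))
    assert sel.n_final == len(sel.features) == 5


def test_select_features_deterministic(small_signal_cohort):
    clinical, omics, y, _ = small_signal_cohort
    cfg = SelectionConfig(method="mdfs1d", seed=13)
    a = select_features(omics["GE"], y, cfg)
    b = select_features(omics["GE"], y, cfg)
    assert a.features == b.features


def test_select_features_empty_is_warning_not_error():
    rng = np.random.default_rng(11)
    t = make_table(rng.standard_normal((80, 50)), modality="GE")
    y = rng.integers(0, 2, 80)
    with pytest.warns(UserWarning, match="no significant"):
        sel = select_features(t, y, SelectionConfig(method="utest", sgof_alpha=1e-9))
    assert sel.empty_warning and sel.features == []


# ---------------------------------------------------------------------------
# Shadow (all-relevant) clinical selection


def test_shadow_select_confirms_label_copy_only():
    rng = np.random.default_rng(12)
    hits = 0
    for seed in range(5):
        y = np.array([0, 1] * 50)
        X = np.column_stack([y + 0.01 * rng.standard_normal(100), rng.standard_normal((100, 10))])
        t = make_table(X, names=["leak"] + [f"n{j}" for j in range(10)])
        confirmed, _ = shadow_select_clinical(t, y, n_iterations=25, alpha=0.01, seed=seed, n_trees=60)
        if confirmed == ["leak"]:
            hits += 1
    assert hits >= 4


def test_shadow_select_all_noise_confirms_nothing():
    rng = np.random.default_rng(13)
    miss = 0
    for seed in range(5):
        X = rng.standard_normal((120, 8))
        y = rng.integers(0, 2, 120)
        confirmed, _ = shadow_select_clinical(make_table(X), y, n_iterations=25, alpha=0.01, seed=seed, n_trees=60)
        if confirmed:
            miss += 1
    assert miss <= 1


def test_shadow_select_strong_vs_noise_block():
    rng = np.random.default_rng(14)
    ok = 0
    for seed in range(5):
        y = rng.integers(0, 2, 250)
        strong = y[:, None] * 1.2 + rng.standard_normal((250, 5))
        noise = rng.standard_normal((250, 5))
        t = make_table(
            np.column_stack([strong, noise]),
            names=[f"s{j}" for j in range(5)] + [f"n{j}" for j in range(5)],
        )
        confirmed, _ = shadow_select_clinical(t, y, n_iterations=30, alpha=0.01, seed=seed, n_trees=80)
        if set(confirmed) == {f"s{j}" for j in range(5)}:
            ok += 1
    assert ok >= 4


def test_shadow_select_rejects_too_few_iterations():
    t = make_table(np.random.default_rng(0).standard_normal((30, 3)))
    with pytest.raises(ValueError):
        shadow_select_clinical(t, np.array([0, 1] * 15), n_iterations=3)
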