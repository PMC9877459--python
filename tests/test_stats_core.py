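"""Unit and property tests for the shared statistical primitives.

Independent oracles live next to the tests: rank-sum enumeration, BH
step-up brute force, AUC pair counting, and the no-ties Spearman formula.
"""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from fflscope.stats_core import (
    benjamini_hochberg,
    hypergeometric_ora,
    roc_auc,
    significance_tier,
    spearman_correlation,
    wilcoxon_rank_sum,
)


# ------------------------------------------------------------------ oracles

def bh_oracle(p):
    """Step-up p*(m/i) with cumulative-min enforcement, clipped at 1."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        i = m - rank_from_top
        running = min(running, p[idx] * m / i)
        adj[idx] = running
    return np.minimum(adj, 1.0)


def auc_pair_oracle(pos, neg):
    wins = sum(1.0 for p in pos for q in neg if p > q)
    ties = sum(0.5 for p in pos for q in neg if p == q)
    return (wins + ties) / (len(pos) * len(neg))


def ranksum_exact_oracle(a, b):
    """Two-sided p by enumerating every assignment of pooled ranks."""
    pooled = sorted(list(a) + list(b))
    n_a = len(a)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    w_obs = sum(ranks[v] for v in a)
    mu = n_a * (len(pooled) + 1) / 2.0
    count = total = 0
    for combo in itertools.combinations(range(1, len(pooled) + 1), n_a):
        total += 1
        if abs(sum(combo) - mu) >= abs(w_obs - mu) - 1e-12:
            count += 1
    return count / total


# ------------------------------------------------------------------ spearman

def test_spearman_perfect_monotone():
    assert spearman_correlation([1, 2, 3], [2, 4, 6]).rho == pytest.approx(1.0)
    assert spearman_correlation([1, 2, 3], [6, 4, 2]).rho == pytest.approx(-1.0)
    # |rho| = 1 reports the smallest representable tail, not zero
    assert 0 < spearman_correlation([1, 2, 3], [2, 4, 6]).p_value < 1e-300


def test_spearman_no_ties_formula():
    # 1 - 6*sum(d^2)/(n(n^2-1)) with sum(d^2) = 4
    res = spearman_correlation([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
    assert res.rho == pytest.approx(0.8)
    t = 0.8 * math.sqrt(3 / (1 - 0.64))
    assert res.p_value == pytest.approx(2 * stats.t.sf(t, df=3))


def test_spearman_drops_missing_pairs():
    res = spearman_correlation([1, 2, 3, np.nan], [2, 4, 6, 5])
    assert res.n == 3
    assert res.rho == pytest.approx(1.0)


@pytest.mark.parametrize(
    "x, y, msg",
    [
        ([1, 2], [1, 2, 3], "length mismatch"),
        ([1, 2], [3, 4], "at least 3"),
        ([1, 1, 1], [1, 2, 3], "zero variance"),
    ],
)
def test_spearman_errors(x, y, msg):
    with pytest.raises(ValueError, match=msg):
        spearman_correlation(x, y)


def test_spearman_monotone_transform_invariance(rng):
    for _ in range(20):
        x = rng.normal(size=15)
        y = rng.normal(size=15)
        base = spearman_correlation(x, y)
        assert spearman_correlation(np.exp(x), y).rho == pytest.approx(base.rho)
        assert spearman_correlation(x, y**3).rho == pytest.approx(base.rho)


# ------------------------------------------------------------------ wilcoxon

def test_ranksum_exact_separated():
    assert wilcoxon_rank_sum([1, 2, 3], [4, 5, 6]).p_value == pytest.approx(0.1)


def test_ranksum_symmetry_and_identical():
    p1 = wilcoxon_rank_sum([1, 5, 9], [2, 3, 8]).p_value
    p2 = wilcoxon_rank_sum([2, 3, 8], [1, 5, 9]).p_value
    assert p1 == pytest.approx(p2)
    assert wilcoxon_rank_sum([5, 5, 5], [5, 5, 5]).p_value == 1.0


def test_ranksum_empty_group_errors():
    with pytest.raises(ValueError):
        wilcoxon_rank_sum([], [1, 2])


def test_ranksum_matches_enumeration_oracle(rng):
    for _ in range(25):
        n_a = int(rng.integers(2, 6))
        n_b = int(rng.integers(2, 11 - n_a))
        pooled = rng.permutation(np.arange(1, n_a + n_b + 1)).astype(float)
        a, b = pooled[:n_a], pooled[n_a:]
        assert wilcoxon_rank_sum(a, b).p_value == pytest.approx(
            ranksum_exact_oracle(a, b), abs=1e-12
        )


# ------------------------------------------------------------------ BH

@pytest.mark.parametrize(
    "p, expected",
    [
        ([0.01, 0.02, 0.03, 0.04, 0.05], [0.05] * 5),
        ([0.5], [0.5]),
        ([0.005, 0.5], [0.01, 0.5]),
    ],
)
def test_bh_examples(p, expected):
    assert benjamini_hochberg(p) == pytest.approx(expected)


def test_bh_matches_oracle_and_properties(rng):
    for _ in range(30):
        p = rng.uniform(size=int(rng.integers(1, 25)))
        adj = benjamini_hochberg(p)
        assert adj == pytest.approx(bh_oracle(p))
        assert np.all(adj >= p - 1e-12)
        assert np.all(adj <= 1.0)
        perm = rng.permutation(p.size)
        assert benjamini_hochberg(p[perm]) == pytest.approx(adj[perm])


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        benjamini_hochberg([0.5, 1.2])


# ------------------------------------------------------------------ ROC

def test_roc_examples():
    assert roc_auc([3, 2, 1, 0], [1, 1, 0, 0]).auc == 1.0
    assert roc_auc([1, 1], [1, 0]).auc == 0.5
    assert roc_auc([2, 0, 1, 1], [1, 1, 0, 0]).auc == 0.5


def test_roc_matches_pair_oracle_and_curve(rng):
    for _ in range(40):
        n_pos = int(rng.integers(1, 9))
        n_neg = int(rng.integers(1, 9))
        pos = rng.integers(0, 6, n_pos).astype(float)
        neg = rng.integers(0, 6, n_neg).astype(float)
        res = roc_auc(
            np.concatenate([pos, neg]),
            np.concatenate([np.ones(n_pos), np.zeros(n_neg)]).astype(int),
        )
        assert res.auc == pytest.approx(auc_pair_oracle(pos, neg))
        curve = res.curve
        assert tuple(curve[0]) == (0.0, 0.0)
        assert tuple(curve[-1]) == (1.0, 1.0)
        assert np.all(np.diff(curve[:, 0]) >= 0)
        assert np.all(np.diff(curve[:, 1]) >= 0)


def test_roc_label_flip_complements_auc(rng):
    for _ in range(20):
        scores = rng.permutation(np.arange(10)).astype(float)  # tie-free
        labels = (rng.random(10) < 0.5).astype(int)
        if labels.min() == labels.max():
            continue
        a = roc_auc(scores, labels).auc
        b = roc_auc(scores, 1 - labels).auc
        assert a + b == pytest.approx(1.0)


def test_roc_single_class_errors():
    with pytest.raises(ValueError):
        roc_auc([1, 2], [1, 1])


# ------------------------------------------------------------------ ORA

def test_hypergeometric_exact_value():
    universe = [f"g{i}" for i in range(10)]
    annotation = universe[:5]
    query = universe[:4]
    res = hypergeometric_ora(query, universe, annotation)
    assert res.p_value == pytest.approx(5 / 210)
    assert res.statistic == 4


def test_hypergeometric_trivial_tails():
    universe = [f"g{i}" for i in range(10)]
    assert hypergeometric_ora(universe[5:9], universe, universe[:5]).p_value == pytest.approx(
        stats.hypergeom.sf(-1, 10, 5, 4)
    )
    assert hypergeometric_ora(universe[5:9], universe, []).p_value == 1.0
    assert hypergeometric_ora(universe, universe, universe[:5]).p_value == 1.0


def test_hypergeometric_validates_containment():
    with pytest.raises(ValueError, match="not contained"):
        hypergeometric_ora(["x"], ["a", "b"], ["a"])
    with pytest.raises(ValueError, match="empty universe"):
        hypergeometric_ora([], [], ["a"])


def test_significance_tiers():
    assert significance_tier(0.0005) == "***"
    assert significance_tier(0.005) == "**"
    assert significance_tier(0.03) == "*"
    assert significance_tier(0.07) == "#"
    assert significance_tier(0.5) == ""
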