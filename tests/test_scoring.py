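"""ssGSEA running-sum scoring, ESTIMATE-style scores and associations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fflscope.io import ExpressionDataset, GeneSetCollection
from fflscope.scoring import (
    estimate_scores,
    group_contrast,
    immune_associations,
    mean_split,
    signature_scores,
    ssgsea_score,
    til_abundances,
    PURITY_INTERCEPT,
    PURITY_SLOPE,
)


def dataset(matrix, features=None):
    X = np.asarray(matrix, dtype=float)
    features = features or [f"g{i}" for i in range(X.shape[0])]
    samples = [f"s{j}" for j in range(X.shape[1])]
    ann = pd.DataFrame({"subtype": ["MTC"] * X.shape[1]}, index=samples)
    return ExpressionDataset(pd.DataFrame(X, index=features, columns=samples), ann)


def ssgsea_oracle(expr, in_set, alpha):
    """Direct running-sum evaluation for one sample."""
    expr = np.asarray(expr, dtype=float)
    n = expr.size
    ranks = stats.rankdata(expr)
    order = sorted(range(n), key=lambda i: (-expr[i], i))
    w_sum = sum(ranks[i] ** alpha for i in order if i in in_set)
    n_out = n - len(in_set)
    p_in = p_out = 0.0
    es = 0.0
    for i in order:
        if i in in_set:
            p_in += ranks[i] ** alpha / w_sum
        else:
            p_out += 1.0 / n_out
        es += p_in - p_out
    return es


def test_single_sample_matches_hand_oracle():
    ds = dataset([[8.0], [6.0], [4.0], [2.0]])
    got = ssgsea_score(ds, {"g0"}, alpha=0.25).iloc[0]
    assert got == pytest.approx(ssgsea_oracle([8, 6, 4, 2], {0}, 0.25))
    # explicit value: top-ranked member contributes immediately
    assert got == pytest.approx(3.0 - (0/3 + 1/3 + 2/3))


def test_matches_oracle_on_random_small_instances(rng):
    for _ in range(30):
        n = int(rng.integers(3, 11))
        x = rng.normal(size=(n, 1))
        k = int(rng.integers(1, n))
        members = set(rng.choice(n, size=k, replace=False).tolist())
        ds = dataset(x)
        got = ssgsea_score(ds, {f"g{i}" for i in members}, alpha=0.25).iloc[0]
        assert got == pytest.approx(ssgsea_oracle(x[:, 0], members, 0.25))


def test_rank_invariances(rng):
    x = rng.normal(7, 1, size=(20, 5))
    ds = dataset(x)
    members = {"g1", "g4", "g7"}
    base = ssgsea_score(ds, members)
    # identical expression vectors give identical scores
    dup = dataset(np.column_stack([x[:, 0], x[:, 0]]))
    s = ssgsea_score(dup, members)
    assert s.iloc[0] == pytest.approx(s.iloc[1])
    # strictly monotone transform leaves scores unchanged
    assert ssgsea_score(dataset(np.exp(x)), members).values == pytest.approx(base.values)
    # adding a constant to one sample leaves its score unchanged
    shifted = x.copy()
    shifted[:, 2] += 5.0
    assert ssgsea_score(dataset(shifted), members).iloc[2] == pytest.approx(base.iloc[2])


def test_set_validation(rng):
    ds = dataset(rng.normal(size=(5, 3)))
    with pytest.raises(ValueError, match="no gene-set member"):
        ssgsea_score(ds, {"absent"})
    with pytest.raises(ValueError, match="covers every feature"):
        ssgsea_score(ds, {f"g{i}" for i in range(5)})
    # partial overlap allowed: absent members are dropped
    full = ssgsea_score(ds, {"g0", "g1"})
    partial = ssgsea_score(ds, {"g0", "g1", "ghost1", "ghost2"})
    assert partial.values == pytest.approx(full.values)


def test_normalization_divides_by_range(rng):
    ds = dataset(rng.normal(size=(30, 8)))
    raw = ssgsea_score(ds, {"g0", "g5"}, normalize=False)
    norm = ssgsea_score(ds, {"g0", "g5"}, normalize=True)
    assert norm.values == pytest.approx((raw / (raw.max() - raw.min())).values)


def test_mean_split_rule():
    s = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
    grp = mean_split(s)
    assert list(grp) == ["low", "low", "high", "high"]
    flat = mean_split(pd.Series([2.0, 2.0], index=list("ab")))
    assert list(flat) == ["low", "low"]  # strictly-greater convention


def test_estimate_sum_and_purity(rng):
    ds = dataset(rng.normal(7, 1, size=(60, 10)))
    stromal = {f"g{i}" for i in range(0, 10)}
    immune = {f"g{i}" for i in range(10, 20)}
    out = estimate_scores(ds, stromal, immune)
    np.testing.assert_allclose(
        out["estimate_score"], out["stromal_score"] + out["immune_score"], rtol=1e-12
    )
    np.testing.assert_allclose(
        out["tumor_purity"], np.cos(PURITY_INTERCEPT + PURITY_SLOPE * out["estimate_score"])
    )
    # zero ESTIMATE score maps to cos of the intercept; purity decreases
    assert np.cos(PURITY_INTERCEPT) == pytest.approx(0.82251, abs=1e-4)
    es = np.linspace(-1000, 3000, 50)
    purity = np.cos(PURITY_INTERCEPT + PURITY_SLOPE * es)
    assert np.all(np.diff(purity) < 0)


def test_signature_scores_with_partial_mirna_set(rng):
    """A signature computed from the members present in the matrix (the
    9-of-13 situation) equals the score of the reduced set."""
    mrna = dataset(rng.normal(size=(40, 6)))
    mir = dataset(rng.normal(size=(13, 6)), features=[f"m{i}" for i in range(13)])
    full = {f"m{i}" for i in range(13)} | {"mghost1", "mghost2", "mghost3", "mghost4"}
    reduced = {f"m{i}" for i in range(12)}  # m12 stays out-of-set
    a = signature_scores(mrna, mir, {"g0"}, {"g1", "g2"}, reduced)
    b = signature_scores(mrna, mir, {"g0"}, {"g1", "g2"}, reduced | {"zz1", "zz2"})
    pd.testing.assert_frame_equal(a, b)


def test_group_contrast_directions(rng):
    groups = pd.Series(["high"] * 10 + ["low"] * 10)
    up = pd.Series(np.r_[rng.normal(5, 0.1, 10), rng.normal(1, 0.1, 10)])
    res, direction = group_contrast(up, groups)
    assert direction == "higher_in_high" and res.p_value < 0.01
    same = pd.Series(np.ones(20))
    res2, dir2 = group_contrast(same, groups)
    assert res2.p_value == 1.0 and dir2 == "none"
    with pytest.raises(ValueError):
        group_contrast(up, pd.Series(["high"] * 19 + ["low"]))


def test_association_table_shape(rng):
    n = 30
    table = pd.DataFrame(
        {
            "tf_score": rng.normal(size=n),
            "hub_score": rng.normal(size=n),
            "mirna_score": rng.normal(size=n),
            "stromal_score": rng.normal(size=n),
            "immune_score": rng.normal(size=n),
            "tumor_purity": rng.normal(size=n),
        },
        index=[f"s{i}" for i in range(n)],
    )
    table["estimate_score"] = table["stromal_score"] + table["immune_score"]
    for sig in ("tf", "hub", "mirna"):
        table[f"{sig}_group"] = mean_split(table[f"{sig}_score"])
    assoc = immune_associations(table)
    assert set(assoc["signature"]) == {"tf", "hub", "mirna"}
    assert {"wilcoxon_p", "rho", "direction"} <= set(assoc.columns)
    assert assoc["wilcoxon_p"].between(0, 1).all()


def test_til_abundance_columns(rng):
    ds = dataset(rng.normal(size=(30, 4)))
    sets = GeneSetCollection({"TIL_01": {"g0", "g1"}, "TIL_02": {"g5", "g6", "g7"}})
    out = til_abundances(ds, sets)
    assert list(out.columns) == ["TIL_01", "TIL_02"]
    assert len(out) == 4
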