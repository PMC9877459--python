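"""Moderated-t differential expression and exclusivity set algebra."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fflscope.diffexpr import (
    DEResult,
    call_degs,
    exclusive_degs,
    fit_variance_prior,
    moderated_de,
)
from fflscope.io import ExpressionDataset


def make_dataset(matrix, groups):
    n = len(groups)
    samples = [f"s{i}" for i in range(n)]
    values = pd.DataFrame(
        np.asarray(matrix, dtype=float),
        index=[f"g{i}" for i in range(np.asarray(matrix).shape[0])],
        columns=samples,
    )
    ann = pd.DataFrame({"subtype": groups}, index=samples)
    return ExpressionDataset(values, ann)


TOY = [
    [5.0, 6.0, 7.0, 1.0, 2.0, 3.0],
    [2.0, 2.5, 3.0, 2.2, 2.4, 2.9],
    [4.0, 4.0, 4.0, 4.0, 4.0, 4.0],
]
TOY_GROUPS = ["T", "T", "T", "N", "N", "N"]


def test_injected_prior_matches_closed_form():
    """With d0=4, s0^2=1 fixed, t_mod equals the posterior-variance formula
    evaluated independently per feature."""
    ds = make_dataset(TOY, TOY_GROUPS)
    res = moderated_de(ds, "T", "N", d0=4.0, s0_sq=1.0)
    X = np.asarray(TOY)
    for i, g in enumerate(["g0", "g1", "g2"]):
        a, b = X[i, :3], X[i, 3:]
        lfc = a.mean() - b.mean()
        s2 = (2 * a.var(ddof=1) + 2 * b.var(ddof=1)) / 4
        post = (4.0 * 1.0 + 4 * s2) / (4.0 + 4)
        expect_t = lfc / np.sqrt(post * (2 / 3)) if lfc != 0 else 0.0
        assert res.table.loc[g, "log2fc"] == pytest.approx(lfc)
        assert res.table.loc[g, "t_mod"] == pytest.approx(expect_t)
        expect_p = 2 * stats.t.sf(abs(expect_t), df=8)
        assert res.table.loc[g, "p_value"] == pytest.approx(expect_p)


def test_zero_prior_df_reduces_to_pooled_t():
    ds = make_dataset(TOY[:2], TOY_GROUPS)
    res = moderated_de(ds, "T", "N", d0=0.0, s0_sq=1.0)
    for i, g in enumerate(["g0", "g1"]):
        t_ref, _ = stats.ttest_ind(TOY[i][:3], TOY[i][3:], equal_var=True)
        assert res.table.loc[g, "t_mod"] == pytest.approx(t_ref)


def test_flat_feature_scores_zero():
    ds = make_dataset(TOY, TOY_GROUPS)
    res = moderated_de(ds, "T", "N", d0=4.0, s0_sq=1.0)
    assert res.table.loc["g2", "log2fc"] == 0.0
    assert res.table.loc["g2", "t_mod"] == 0.0


def test_group_swap_negates_effects(rng):
    mat = rng.normal(7, 1, (50, 12))
    groups = ["A"] * 6 + ["B"] * 6
    ds = make_dataset(mat, groups)
    ab = moderated_de(ds, "A", "B")
    ba = moderated_de(ds, "B", "A")
    np.testing.assert_allclose(ab.table["log2fc"], -ba.table["log2fc"])
    np.testing.assert_allclose(ab.table["t_mod"], -ba.table["t_mod"])


def test_sample_order_invariance(rng):
    mat = rng.normal(7, 1, (30, 10))
    groups = ["A", "B"] * 5
    ds = make_dataset(mat, groups)
    perm = rng.permutation(10)
    shuffled = ExpressionDataset(ds.values.iloc[:, perm], ds.annotations.iloc[perm])
    a = moderated_de(ds, "A", "B").table
    b = moderated_de(shuffled, "A", "B").table
    np.testing.assert_allclose(a["t_mod"], b["t_mod"])


def test_small_group_errors():
    ds = make_dataset([[1.0, 2.0, 3.0]], ["A", "B", "B"])
    with pytest.raises(ValueError, match=">= 2 samples"):
        moderated_de(ds, "A", "B")
    with pytest.raises(ValueError, match=">= 2 samples"):
        moderated_de(ds, "C", "B")


def test_variance_prior_recovers_on_simulated_chisq(rng):
    """Moment matching approximately recovers a known (d0, s0^2) from
    scaled-inverse-chi-square draws."""
    d0_true, s0_true, df = 6.0, 1.5, 4
    n = 4000
    true_vars = d0_true * s0_true / rng.chisquare(d0_true, n)
    sample_vars = true_vars * rng.chisquare(df, n) / df
    d0, s0 = fit_variance_prior(sample_vars, df)
    assert d0 == pytest.approx(d0_true, rel=0.25)
    assert s0 == pytest.approx(s0_true, rel=0.15)


# ------------------------------------------------------------- DEG calling

def _result_from(adj_p, lfc):
    table = pd.DataFrame(
        {
            "log2fc": lfc,
            "t_mod": np.sign(lfc),
            "p_value": adj_p,
            "adj_p": adj_p,
            "call": "none",
        },
        index=[f"g{i}" for i in range(len(lfc))],
    )
    return DEResult(table=table, group_a="T", group_b="N", d0=1, s0_sq=1)


def test_call_thresholds_follow_quoted_rules():
    res = _result_from([0.049, 0.05, 0.01], [1.0, 3.0, -0.99])
    up, down = call_degs(res, p_cut=0.05, lfc_cut=1.0)
    assert up == {"g0"}      # adj_p 0.049, lfc exactly 1.0: inclusive
    assert "g1" not in up    # adj_p exactly 0.05: strict
    assert down == set()     # |lfc| 0.99 below cutoff 1
    up2, down2 = call_degs(res, p_cut=0.05, lfc_cut=0.58)
    assert down2 == {"g2"}   # same gene passes the miRNA regime


def test_call_degenerate_thresholds():
    res = _result_from([0.001, 0.002, 0.5], [2.0, -0.1, 0.0])
    assert call_degs(res, p_cut=0.0, lfc_cut=0.0) == (set(), set())
    up, down = call_degs(res, p_cut=1.0, lfc_cut=0.0)
    assert up == {"g0"} and down == {"g1"}  # lfc 0 excluded from both


# ------------------------------------------------------------- exclusivity

def test_exclusive_set_algebra():
    calls = {
        "MTC": ({"a", "b", "c"}, {"d"}),
        "ATC": ({"b"}, set()),
    }
    res = exclusive_degs(calls, "MTC")
    assert res.exclusive_up == {"a", "c"}
    assert res.exclusive_down == {"d"}
    res2 = exclusive_degs(calls, "MTC", second_cohort_degs={"a", "d"})
    assert res2.post_exclusion_up == {"c"}
    assert res2.post_exclusion_down == set()


def test_direction_agnostic_disqualification():
    """A gene up in the target but down in a comparator is not exclusive."""
    calls = {
        "MTC": ({"x", "y"}, set()),
        "PTC": (set(), {"x"}),
    }
    res = exclusive_degs(calls, "MTC")
    assert res.exclusive_up == {"y"}


def test_merge_plan_unions_comparators():
    calls = {
        "MTC": ({"a", "b", "c"}, set()),
        "PTC": ({"a"}, set()),
        "FTC": (set(), {"b"}),
        "ATC": (set(), set()),
    }
    res = exclusive_degs(calls, "MTC", merge_plan={"WDTC": ["PTC", "FTC"]})
    assert res.exclusive_up == {"c"}
    assert set(res.per_subtype_up) == {"MTC", "WDTC", "ATC"}


def test_target_cannot_be_comparator():
    calls = {"MTC": ({"a"}, set()), "PTC": (set(), set())}
    with pytest.raises(ValueError, match="cannot be merged"):
        exclusive_degs(calls, "MTC", merge_plan={"X": ["MTC", "PTC"]})
    with pytest.raises(ValueError, match="no DEG calls"):
        exclusive_degs(calls, "XYZ")


def test_invariant_exclusive_subset_chain():
    calls = {
        "MTC": ({"a", "b"}, {"c", "d"}),
        "ATC": ({"b", "c"}, set()),
    }
    res = exclusive_degs(calls, "MTC", second_cohort_degs={"d"})
    assert res.exclusive_up <= calls["MTC"][0]
    assert res.exclusive_down <= calls["MTC"][1]
    assert res.post_exclusion_up <= res.exclusive_up
    assert res.post_exclusion_down <= res.exclusive_down
    assert not res.exclusive_up & res.exclusive_down
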