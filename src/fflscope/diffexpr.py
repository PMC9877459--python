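"""Moderated two-group differential expression and subtype-exclusivity algebra.

The per-feature test is a two-sample comparison on the log2 scale with
empirical-Bayes variance moderation: the prior degrees of freedom d0 and
prior variance s0^2 are estimated by moment matching on the log sample
variances across features (the classic limma-style squeeze), the posterior
variance is

    s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g),

and the moderated t uses d0 + d_g degrees of freedom. DEG calling applies a
strict adjusted-p cutoff and an inclusive |log2FC| cutoff; exclusivity is
plain set algebra over per-subtype DEG lists with optional comparator
merging and a second-cohort subtraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from fflscope.io import ExpressionDataset, BATCH_COL
from fflscope.stats_core import benjamini_hochberg


@dataclass
class DEResult:
    """Per-feature differential-expression table for one contrast."""

    table: pd.DataFrame  # columns: log2fc, t_mod, p_value, adj_p, call
    group_a: str
    group_b: str
    d0: float
    s0_sq: float

    def up_set(self) -> set[str]:
        return set(self.table.index[self.table["call"] == "up"])

    def down_set(self) -> set[str]:
        return set(self.table.index[self.table["call"] == "down"])

    def deg_set(self) -> set[str]:
        return self.up_set() | self.down_set()


@dataclass
class ExclusivityResult:
    """Per-subtype DEG sets and the target subtype's exclusivity algebra."""

    per_subtype_up: dict[str, set[str]]
    per_subtype_down: dict[str, set[str]]
    target: str
    exclusive_up: set[str]
    exclusive_down: set[str]
    post_exclusion_up: set[str]
    post_exclusion_down: set[str]
    step_sizes: dict[str, int] = field(default_factory=dict)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        raise ValueError("trigamma inverse needs y > 0")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def fit_variance_prior(sample_vars: np.ndarray, df_resid: float) -> tuple[float, float]:
    """Moment-match (d0, s0^2) on the log sample variances.

    Positive variances only; returns (inf, geometric-mean variance) when the
    observed spread of log variances is no larger than expected from the
    chi-square sampling noise alone.
    """
    s2 = np.asarray(sample_vars, dtype=float)
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if s2.size < 2:
        return np.inf, float(np.mean(s2)) if s2.size else 1.0
    z = np.log(s2)
    e = z - special.digamma(df_resid / 2.0) + np.log(df_resid / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) - float(special.polygamma(1, df_resid / 2.0))
    if e_var <= 0:
        return np.inf, float(np.exp(e_mean))
    d0 = 2.0 * _trigamma_inverse(e_var)
    s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def _batch_center(values: pd.DataFrame, batches: pd.Series) -> pd.DataFrame:
    """Subtract each batch's per-feature median (light batch adjustment)."""
    out = values.copy()
    for b in batches.unique():
        cols = batches.index[batches == b]
        out[cols] = out[cols].sub(out[cols].median(axis=1), axis=0)
    return out


def moderated_de(
    dataset: ExpressionDataset,
    group_a: str,
    group_b: str,
    d0: float | None = None,
    s0_sq: float | None = None,
    batch_center: bool = False,
) -> DEResult:
    """Moderated-t differential expression of ``group_a`` minus ``group_b``.

    ``d0``/``s0_sq`` may be injected to bypass the moment-matching estimate
    (``d0=0`` reduces to the ordinary pooled-variance t-test).
    """
    subtypes = dataset.subtypes()
    for g in (group_a, group_b):
        if (subtypes == g).sum() < 2:
            raise ValueError(f"group {g!r} needs >= 2 samples")
    values = dataset.values
    if batch_center:
        if BATCH_COL not in dataset.annotations.columns:
            raise ValueError("batch centering requested but no batch column")
        values = _batch_center(values, dataset.annotations[BATCH_COL])

    a = values.loc[:, subtypes == group_a].to_numpy(dtype=float)
    b = values.loc[:, subtypes == group_b].to_numpy(dtype=float)
    na, nb = a.shape[1], b.shape[1]
    mean_a = np.nanmean(a, axis=1)
    mean_b = np.nanmean(b, axis=1)
    lfc = mean_a - mean_b
    var_a = np.nanvar(a, axis=1, ddof=1)
    var_b = np.nanvar(b, axis=1, ddof=1)
    df_resid = na + nb - 2
    pooled = ((na - 1) * var_a + (nb - 1) * var_b) / df_resid

    if d0 is None or s0_sq is None:
        d0_est, s0_est = fit_variance_prior(pooled, df_resid)
        d0 = d0_est if d0 is None else d0
        s0_sq = s0_est if s0_sq is None else s0_sq

    if np.isinf(d0):
        post_var = np.full_like(pooled, s0_sq)
        df_total = np.inf
    else:
        post_var = (d0 * s0_sq + df_resid * pooled) / (d0 + df_resid)
        df_total = d0 + df_resid

    se = np.sqrt(post_var * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = np.where(se > 0, lfc / np.where(se > 0, se, 1.0), 0.0)
    t_mod = np.where((lfc == 0), 0.0, t_mod)
    p = 2.0 * stats.t.sf(np.abs(t_mod), df=df_total)
    p = np.clip(p, 0.0, 1.0)
    adj = benjamini_hochberg(p)

    table = pd.DataFrame(
        {"log2fc": lfc, "t_mod": t_mod, "p_value": p, "adj_p": adj, "call": "none"},
        index=values.index,
    )
    return DEResult(table=table, group_a=group_a, group_b=group_b,
                    d0=float(d0), s0_sq=float(s0_sq))


def call_degs(de: DEResult, p_cut: float, lfc_cut: float) -> tuple[set[str], set[str]]:
    """Call DEGs: strict adj_p < p_cut, inclusive |log2FC| >= lfc_cut.

    Also rewrites the ``call`` column of the result table in place.
    """
    if not (0 <= p_cut <= 1) or lfc_cut < 0:
        raise ValueError("thresholds out of range")
    t = de.table
    sig = t["adj_p"] < p_cut
    up = set(t.index[sig & (t["log2fc"] >= lfc_cut) & (t["log2fc"] != 0)])
    down = set(t.index[sig & (t["log2fc"] <= -lfc_cut) & (t["log2fc"] != 0)])
    t["call"] = "none"
    t.loc[list(up), "call"] = "up"
    t.loc[list(down), "call"] = "down"
    return up, down


def exclusive_degs(
    per_subtype_calls: dict[str, tuple[set[str], set[str]]],
    target: str,
    merge_plan: dict[str, list[str]] | None = None,
    second_cohort_degs: set[str] | None = None,
) -> ExclusivityResult:
    """Target-subtype exclusivity by direction-agnostic set subtraction.

    ``merge_plan`` maps a merged comparator name to member subtypes whose
    DEG sets are unioned (e.g. WDTC = PTC + FTC + OTC). A gene DE in any
    comparator, in either direction, is disqualified. ``second_cohort_degs``
    is subtracted afterwards.
    """
    if target not in per_subtype_calls:
        raise ValueError(f"target {target!r} has no DEG calls")
    merge_plan = merge_plan or {}
    merged: dict[str, tuple[set[str], set[str]]] = {}
    consumed: set[str] = set()
    for name, members in merge_plan.items():
        if target in members:
            raise ValueError("target cannot be merged into a comparator")
        ups, downs = set(), set()
        for m in members:
            mu, md = per_subtype_calls[m]
            ups |= mu
            downs |= md
            consumed.add(m)
        merged[name] = (ups, downs)
    for name, calls in per_subtype_calls.items():
        if name not in consumed and name != target:
            merged[name] = calls

    target_up, target_down = per_subtype_calls[target]
    comparator_union: set[str] = set()
    for ups, downs in merged.values():
        comparator_union |= ups | downs

    exclusive_up = target_up - comparator_union
    exclusive_down = target_down - comparator_union
    second = second_cohort_degs or set()
    post_up = exclusive_up - second
    post_down = exclusive_down - second

    per_up = {target: target_up, **{k: v[0] for k, v in merged.items()}}
    per_down = {target: target_down, **{k: v[1] for k, v in merged.items()}}
    steps = {
        "target_up": len(target_up),
        "target_down": len(target_down),
        "comparator_union": len(comparator_union),
        "exclusive_up": len(exclusive_up),
        "exclusive_down": len(exclusive_down),
        "post_exclusion_up": len(post_up),
        "post_exclusion_down": len(post_down),
    }
    return ExclusivityResult(
        per_subtype_up=per_up,
        per_subtype_down=per_down,
        target=target,
        exclusive_up=exclusive_up,
        exclusive_down=exclusive_down,
        post_exclusion_up=post_up,
        post_exclusion_down=post_down,
        step_sizes=steps,
    )
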