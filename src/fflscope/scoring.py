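"""Per-sample signature scoring and immune-environment statistics.

ssGSEA: for one sample, features are ranked by expression (descending,
average ranks for ties); the enrichment score is the sum over the ranked
list of the difference between the weighted in-set cumulative distribution
(weights rank^alpha, normalized to one) and the unweighted out-of-set
cumulative. TF / hub-gene / miRNA signature scores are range-normalized
across the sample batch; stromal and immune scores are left unnormalized
and combined as ESTIMATE = stromal + immune, with tumor purity from the
published cosine formula

    purity = cos(0.6049872018 + 0.0001467884 * ESTIMATE).

Samples are split into high/low groups at the mean score; group contrasts
use the Wilcoxon rank-sum test and continuous associations Spearman
correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from fflscope.io import ExpressionDataset, GeneSetCollection
from fflscope.stats_core import (
    TestResult,
    significance_tier,
    spearman_correlation,
    wilcoxon_rank_sum,
)

logger = logging.getLogger("fflscope")

PURITY_INTERCEPT = 0.6049872018
PURITY_SLOPE = 0.0001467884


def ssgsea_score(
    dataset: ExpressionDataset,
    gene_set: set[str],
    alpha: float = 0.25,
    normalize: bool = False,
) -> pd.Series:
    """ssGSEA enrichment score per sample for one gene set.

    Set members absent from the matrix are dropped with a warning. With
    ``normalize`` the whole batch of scores is divided by its range
    (max - min across samples).
    """
    present = sorted(gene_set & set(dataset.values.index))
    n_missing = len(gene_set) - len(present)
    if n_missing:
        logger.warning("gene set: %d of %d members absent from matrix", n_missing, len(gene_set))
    if not present:
        raise ValueError("no gene-set member present in the matrix")
    if len(present) >= dataset.n_features:
        raise ValueError("gene set covers every feature; out-of-set is empty")

    X = dataset.values.to_numpy(dtype=float)
    n_features, n_samples = X.shape
    in_set = np.zeros(n_features, dtype=bool)
    pos = {f: i for i, f in enumerate(dataset.values.index)}
    for g in present:
        in_set[pos[g]] = True
    n_out = n_features - in_set.sum()

    scores = np.empty(n_samples)
    for j in range(n_samples):
        x = X[:, j]
        ranks = stats.rankdata(x)  # average ranks, 1 = lowest expression
        order = np.lexsort((np.arange(n_features), -x))  # descending, stable
        s = in_set[order]
        w = ranks[order] ** alpha
        w_in = np.where(s, w, 0.0)
        p_in = np.cumsum(w_in) / w_in.sum()
        p_out = np.cumsum(~s) / n_out
        scores[j] = np.sum(p_in - p_out)

    out = pd.Series(scores, index=dataset.values.columns, name="ssgsea")
    if normalize:
        rng = out.max() - out.min()
        if rng > 0:
            out = out / rng
    return out


def mean_split(scores: pd.Series) -> pd.Series:
    """'high' for scores strictly greater than the mean, else 'low'."""
    return pd.Series(
        np.where(scores > scores.mean(), "high", "low"), index=scores.index, name="group"
    )


@dataclass
class ScoreTable:
    """Per-sample signature scores, group labels and immune quantities."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        cols = set(self.table.columns)
        if {"stromal_score", "immune_score", "estimate_score"} <= cols:
            resid = (
                self.table["stromal_score"] + self.table["immune_score"]
                - self.table["estimate_score"]
            )
            if not np.allclose(resid, 0.0):
                raise ValueError("estimate_score must equal stromal + immune")

    def group(self, signature: str) -> pd.Series:
        return self.table[f"{signature}_group"]


def signature_scores(
    mrna: ExpressionDataset,
    mirna: ExpressionDataset,
    tf_set: set[str],
    hub_set: set[str],
    mirna_set: set[str],
    alpha: float = 0.25,
    normalize: bool = True,
) -> pd.DataFrame:
    """TF / hub / miRNA ssGSEA scores with mean-split group labels."""
    out = pd.DataFrame(index=mrna.values.columns)
    for name, dataset, members in (
        ("tf", mrna, tf_set),
        ("hub", mrna, hub_set),
        ("mirna", mirna, mirna_set),
    ):
        s = ssgsea_score(dataset, members, alpha=alpha, normalize=normalize)
        out[f"{name}_score"] = s
        out[f"{name}_group"] = mean_split(s)
    return out


def estimate_scores(
    dataset: ExpressionDataset,
    stromal_set: set[str],
    immune_set: set[str],
    alpha: float = 0.25,
) -> pd.DataFrame:
    """Unnormalized stromal/immune ssGSEA scores, their sum and purity."""
    stromal = ssgsea_score(dataset, stromal_set, alpha=alpha, normalize=False)
    immune = ssgsea_score(dataset, immune_set, alpha=alpha, normalize=False)
    est = stromal + immune
    purity = np.cos(PURITY_INTERCEPT + PURITY_SLOPE * est)
    return pd.DataFrame(
        {
            "stromal_score": stromal,
            "immune_score": immune,
            "estimate_score": est,
            "tumor_purity": purity,
        }
    )


def til_abundances(
    dataset: ExpressionDataset, til_sets: GeneSetCollection, alpha: float = 0.25
) -> pd.DataFrame:
    """ssGSEA abundance per sample for each infiltrating-cell gene set."""
    cols = {}
    for name in til_sets.names():
        cols[name] = ssgsea_score(dataset, til_sets[name], alpha=alpha, normalize=False)
    return pd.DataFrame(cols)


def group_contrast(values: pd.Series, groups: pd.Series) -> tuple[TestResult, str]:
    """Wilcoxon high-vs-low contrast with a direction label."""
    hi = values[groups == "high"]
    lo = values[groups == "low"]
    if len(hi) < 2 or len(lo) < 2:
        raise ValueError("need >= 2 samples per group")
    res = wilcoxon_rank_sum(hi, lo)
    if hi.median() > lo.median():
        direction = "higher_in_high"
    elif hi.median() < lo.median():
        direction = "lower_in_high"
    else:
        direction = "none"
    if res.p_value >= 1.0:
        direction = "none"
    return res, direction


def immune_associations(
    score_table: pd.DataFrame,
    signatures: tuple[str, ...] = ("tf", "hub", "mirna"),
    quantities: list[str] | None = None,
) -> pd.DataFrame:
    """Signature-by-quantity association table.

    Each immune quantity is contrasted between the signature's high/low
    groups (Wilcoxon) and correlated with the continuous score (Spearman);
    rows carry the statistic, p, significance tier and direction.
    """
    if quantities is None:
        quantities = [
            c for c in score_table.columns
            if not c.endswith(("_score", "_group")) or c in
            ("stromal_score", "immune_score", "estimate_score")
        ]
        quantities = [c for c in quantities if score_table[c].dtype.kind in "fi"]
    rows = []
    for sig in signatures:
        groups = score_table[f"{sig}_group"]
        score = score_table[f"{sig}_score"]
        for q in quantities:
            v = score_table[q].astype(float)
            test, direction = group_contrast(v, groups)
            corr = spearman_correlation(score, v)
            rows.append(
                {
                    "signature": sig,
                    "quantity": q,
                    "wilcoxon_p": test.p_value,
                    "wilcoxon_tier": significance_tier(test.p_value),
                    "direction": direction,
                    "rho": corr.rho,
                    "rho_p": corr.p_value,
                    "rho_tier": significance_tier(corr.p_value),
                }
            )
    return pd.DataFrame(rows)
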