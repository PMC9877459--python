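"""Primitive statistics shared by every pipeline stage.

Thin, strictly-validated wrappers around scipy / statsmodels routines:
Spearman rank correlation, Wilcoxon rank-sum, Benjamini-Hochberg adjustment,
ROC/AUC by pair counting, and hypergeometric over-representation. Ties are
handled with average ranks throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

# Reporting tiers used in association tables: p < 0.1 (#), 0.05 (*),
# 0.01 (**), 0.001 (***).
SIGNIFICANCE_TIERS: tuple[tuple[float, str], ...] = (
    (0.001, "***"),
    (0.01, "**"),
    (0.05, "*"),
    (0.1, "#"),
)


def significance_tier(p: float) -> str:
    """Symbol for the smallest tier threshold that ``p`` clears ('' if none)."""
    for cut, symbol in SIGNIFICANCE_TIERS:
        if p < cut:
            return symbol
    return ""


@dataclass(frozen=True)
class CorrelationResult:
    """Spearman rank correlation with its t-approximation p-value."""

    rho: float
    p_value: float
    n: int


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str


@dataclass(frozen=True)
class ROCResult:
    auc: float
    n_pos: int
    n_neg: int
    curve: np.ndarray = field(repr=False)  # (k, 2) array of (FPR, TPR)


def _as_float_array(v, name: str) -> np.ndarray:
    arr = np.asarray(v, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError(f"{name} is empty")
    return arr


def spearman_correlation(x, y) -> CorrelationResult:
    """Spearman rho with two-sided p from the t-approximation.

    Pairs with a missing value in either vector are dropped before ranking.
    The p-value uses t = rho*sqrt((n-2)/(1-rho^2)) on n-2 degrees of
    freedom; |rho| = 1 is reported with the smallest positive normal float
    as its tail (exact permutation p-values are not implemented).

    Raises
    ------
    ValueError
        on length mismatch, fewer than 3 complete pairs, or zero variance
        in either rank vector (rho undefined).
    """
    xa = np.asarray(x, dtype=float).ravel()
    ya = np.asarray(y, dtype=float).ravel()
    if xa.size != ya.size:
        raise ValueError(f"length mismatch: {xa.size} vs {ya.size}")
    keep = np.isfinite(xa) & np.isfinite(ya)
    xa, ya = xa[keep], ya[keep]
    n = int(xa.size)
    if n < 3:
        raise ValueError(f"need at least 3 complete pairs, got {n}")
    rx = stats.rankdata(xa)
    ry = stats.rankdata(ya)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise ValueError("zero variance in a rank vector; rho undefined")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    rho = max(-1.0, min(1.0, rho))
    if abs(rho) >= 1.0:
        p = float(np.finfo(float).tiny)
    else:
        t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
        p = max(p, float(np.finfo(float).tiny))
    return CorrelationResult(rho=rho, p_value=min(p, 1.0), n=n)


def wilcoxon_rank_sum(a, b) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact enumeration when n_a + n_b <= 20 and the pooled sample is
    tie-free; otherwise the normal approximation with tie and continuity
    corrections.
    """
    aa = _as_float_array(a, "a")
    bb = _as_float_array(b, "b")
    pooled = np.concatenate([aa, bb])
    no_ties = np.unique(pooled).size == pooled.size
    if np.ptp(pooled) == 0:
        # identical constant samples: maximal two-sided tail
        return TestResult(statistic=float(aa.size * bb.size / 2.0), p_value=1.0, method="wilcoxon")
    method = "exact" if (pooled.size <= 20 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(aa, bb, alternative="two-sided", method=method)
    return TestResult(statistic=float(res.statistic), p_value=float(min(res.pvalue, 1.0)), method="wilcoxon")


def benjamini_hochberg(p_values) -> np.ndarray:
    """Step-up FDR adjustment; output order matches input order."""
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def roc_auc(scores, labels, flip: bool = False) -> ROCResult:
    """ROC curve and AUC with higher scores indicating the positive class.

    AUC is the Mann-Whitney pair statistic
    (#(pos > neg) + 0.5 * #(pos == neg)) / (n_pos * n_neg), computed via
    average ranks. Set ``flip`` when lower scores mark positives.
    """
    s = _as_float_array(scores, "scores")
    y = np.asarray(labels).ravel().astype(int)
    if s.size != y.size:
        raise ValueError("scores and labels differ in length")
    if not set(np.unique(y)) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if flip:
        s = -s
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(s)
    auc = (float(np.sum(ranks[y == 1])) - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    # curve: sweep thresholds from +inf down over distinct scores
    order = np.argsort(-s, kind="stable")
    ss, yy = s[order], y[order]
    fpr = [0.0]
    tpr = [0.0]
    tp = fp = 0
    i = 0
    while i < ss.size:
        j = i
        while j < ss.size and ss[j] == ss[i]:
            tp += int(yy[j] == 1)
            fp += int(yy[j] == 0)
            j += 1
        fpr.append(fp / n_neg)
        tpr.append(tp / n_pos)
        i = j
    curve = np.column_stack([fpr, tpr])
    return ROCResult(auc=float(auc), n_pos=n_pos, n_neg=n_neg, curve=curve)


def hypergeometric_ora(query, universe, annotation) -> TestResult:
    """Over-representation p = P(X >= k) for the query/annotation overlap.

    The annotation is intersected with the universe before testing; the
    query must be contained in the universe.
    """
    q = set(query)
    u = set(universe)
    if not u:
        raise ValueError("empty universe")
    if not q <= u:
        missing = sorted(q - u)[:5]
        raise ValueError(f"query not contained in universe (e.g. {missing})")
    ann = set(annotation) & u
    k = len(q & ann)
    # hypergeom.sf(k-1) = P(X >= k)
    p = float(stats.hypergeom.sf(k - 1, len(u), len(ann), len(q)))
    return TestResult(statistic=float(k), p_value=min(p, 1.0), method="hypergeometric")
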