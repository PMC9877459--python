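"""Survival stratification: log-rank tests, optimal cutpoints and Cox models.

The univariate route splits a continuous score at the cutoff maximizing the
two-group log-rank statistic over all admissible candidate cutoffs
(midpoints between consecutive distinct scores leaving at least a
``minprop`` fraction of samples on each side); no maximally-selected-
statistic p-value correction is applied, so the reported log-rank p is
anti-conservative — a documented caveat. The multivariate route fits a
proportional-hazards model by partial-likelihood Newton iteration with
Efron tie handling (via lifelines), adjusting the signature score for
stromal score, immune score and tumor purity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.statistics import logrank_test as _ll_logrank

from fflscope.stats_core import TestResult, significance_tier

logger = logging.getLogger("fflscope")


@dataclass(frozen=True)
class CutpointResult:
    cutoff: float
    statistic: float
    p_value: float
    n_low: int
    n_high: int


@dataclass
class CoxResult:
    """Per-covariate log-hazard coefficients with Wald inference."""

    table: pd.DataFrame  # columns: coef, hr, ci_low, ci_high, p

    def hr(self, covariate: str) -> float:
        return float(self.table.loc[covariate, "hr"])


def logrank_test(time, event, group) -> TestResult:
    """Two-group log-rank chi-square (1 df) on pooled event times."""
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    g = np.asarray(group)
    labels = np.unique(g)
    if labels.size != 2:
        raise ValueError(f"need exactly 2 groups, got {labels.size}")
    if e.sum() == 0:
        raise ValueError("no events")
    mask = g == labels[0]
    res = _ll_logrank(t[mask], t[~mask], event_observed_A=e[mask], event_observed_B=e[~mask])
    return TestResult(statistic=float(res.test_statistic), p_value=float(res.p_value),
                      method="logrank")


def candidate_cutoffs(score: np.ndarray, minprop: float) -> list[float]:
    """Midpoints between consecutive distinct scores respecting minprop."""
    s = np.sort(np.asarray(score, dtype=float))
    n = s.size
    distinct = np.unique(s)
    out = []
    for lo, hi in zip(distinct[:-1], distinct[1:]):
        cut = (lo + hi) / 2.0
        n_low = int(np.sum(s <= cut))
        if minprop <= n_low / n <= 1 - minprop:
            out.append(cut)
    return out


def optimal_cutpoint(score, time, event, minprop: float = 0.1) -> CutpointResult:
    """Cutoff maximizing the log-rank statistic over admissible splits.

    Ties in the statistic are broken toward the more balanced split, then
    toward the lower cutoff.
    """
    s = np.asarray(score, dtype=float)
    if np.unique(s).size < 2:
        raise ValueError("constant scores admit no cutpoint")
    cuts = candidate_cutoffs(s, minprop)
    if not cuts:
        raise ValueError("no admissible cutoff under minprop")
    best: tuple[float, int, float] | None = None  # (-stat, imbalance, cut)
    best_res: CutpointResult | None = None
    for cut in cuts:
        grp = s > cut
        res = logrank_test(time, event, grp)
        n_high = int(grp.sum())
        n_low = int(grp.size - n_high)
        key = (-res.statistic, abs(n_high - n_low), cut)
        if best is None or key < best:
            best = key
            best_res = CutpointResult(cutoff=float(cut), statistic=res.statistic,
                                      p_value=res.p_value, n_low=n_low, n_high=n_high)
    assert best_res is not None
    return best_res


def cox_fit(data: pd.DataFrame, covariates: list[str],
            time_col: str = "time", event_col: str = "event") -> CoxResult:
    """Proportional-hazards fit (Efron ties) with Wald CIs per covariate."""
    for c in covariates:
        if data[c].std(ddof=0) == 0:
            raise ValueError(f"covariate {c!r} has zero variance")
    if data[event_col].sum() == 0:
        raise ValueError("no events")
    cph = CoxPHFitter()
    cph.fit(data[[time_col, event_col] + covariates], duration_col=time_col,
            event_col=event_col)
    coefs = cph.params_
    # separation check on the per-SD scale so small-unit covariates with
    # legitimately large per-unit coefficients do not trip it
    sds = data[covariates].std(ddof=0)
    scaled = (coefs * sds).abs()
    if (scaled > 15).any():
        bad = list(scaled.index[scaled > 15])
        raise ValueError(f"diverging coefficients (possible separation): {bad}")
    summary = cph.summary
    table = pd.DataFrame(
        {
            "coef": summary["coef"],
            "hr": summary["exp(coef)"],
            "ci_low": summary["exp(coef) lower 95%"],
            "ci_high": summary["exp(coef) upper 95%"],
            "p": summary["p"],
        }
    )
    table.index.name = "covariate"
    return CoxResult(table=table)


def survival_report(
    data: pd.DataFrame,
    variables: list[str],
    adjustment: list[str] | None = None,
    endpoint: str = "OS",
    minprop: float = 0.1,
    time_col: str = "time",
    event_col: str = "event",
) -> pd.DataFrame:
    """Univariate (optimal cutpoint + log-rank) and multivariate rows.

    The univariate direction says which side of the cutoff fares better,
    judged by the sign of a Cox fit on the high-group indicator. The
    multivariate row adjusts each variable for the ``adjustment`` columns
    (typically stromal score, immune score and tumor purity).
    """
    rows = []
    for var in variables:
        cp = optimal_cutpoint(data[var], data[time_col], data[event_col], minprop=minprop)
        ind = (data[var] > cp.cutoff).astype(float)
        uni = cox_fit(data.assign(_high=ind), ["_high"], time_col, event_col)
        hr_high = uni.hr("_high")
        rows.append(
            {
                "variable": var,
                "endpoint": endpoint,
                "analysis": "univariate",
                "cutoff": cp.cutoff,
                "statistic": cp.statistic,
                "hr": hr_high,
                "ci_low": float(uni.table.loc["_high", "ci_low"]),
                "ci_high": float(uni.table.loc["_high", "ci_high"]),
                "p": cp.p_value,
                "tier": significance_tier(cp.p_value),
                "direction": "high_better" if hr_high < 1 else "low_better",
            }
        )
        if adjustment:
            multi = cox_fit(data, [var] + list(adjustment), time_col, event_col)
            row = multi.table.loc[var]
            rows.append(
                {
                    "variable": var,
                    "endpoint": endpoint,
                    "analysis": "multivariate",
                    "cutoff": np.nan,
                    "statistic": np.nan,
                    "hr": float(row["hr"]),
                    "ci_low": float(row["ci_low"]),
                    "ci_high": float(row["ci_high"]),
                    "p": float(row["p"]),
                    "tier": significance_tier(float(row["p"])),
                    "direction": "protective" if row["hr"] < 1 else "adverse",
                }
            )
    return pd.DataFrame(rows)
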