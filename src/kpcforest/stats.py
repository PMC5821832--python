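"""Rank-based validation of important variables across sample groups.

Implements the tie-corrected Kruskal-Wallis H test (p-value from the
chi-squared approximation with k-1 degrees of freedom) and the quartile
summaries needed to draw per-group box plots.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.stats import chi2, rankdata

from .kpca import QuadrantLabeling
from .preprocess import FeatureMatrix


class StatsError(ValueError):
    pass


@dataclass
class GroupTestResult:
    variable: str
    h: float
    df: int
    pvalue: float
    tier: str  # ns / * / ** / ***


def significance_tier(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def kruskal_wallis(
    values: Sequence[float],
    groups: Sequence,
    variable: str = "",
) -> GroupTestResult:
    """Tie-corrected Kruskal-Wallis H across >=2 groups.

    H = [12/(N(N+1)) * sum_j R_j^2/n_j - 3(N+1)] / C with the tie correction
    C = 1 - sum(t^3 - t)/(N^3 - N).  When every observation is identical the
    correction degenerates; H is defined as 0 with p = 1.
    """
    x = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    if x.shape != g.shape:
        raise StatsError("values and groups must have equal length")
    labels = np.unique(g)
    if labels.size < 2:
        raise StatsError("need at least 2 groups")
    N = x.size
    ranks = rankdata(x)
    h = 0.0
    for lab in labels:
        r = ranks[g == lab]
        h += r.sum() ** 2 / r.size
    h = 12.0 / (N * (N + 1)) * h - 3.0 * (N + 1)
    _, tie_counts = np.unique(x, return_counts=True)
    correction = 1.0 - np.sum(tie_counts**3 - tie_counts) / (N**3 - N)
    if correction <= 0:
        h, p = 0.0, 1.0
    else:
        h = h / correction
        h = max(h, 0.0)  # guard tiny negative round-off
        p = float(chi2.sf(h, labels.size - 1))
    return GroupTestResult(
        variable=variable,
        h=float(h),
        df=int(labels.size - 1),
        pvalue=float(p),
        tier=significance_tier(p),
    )


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """BH-adjusted p-values (monotone step-up)."""
    p = np.asarray(pvalues, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    adj = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(adj, 0, 1)
    return out


def kw_table(
    matrix: FeatureMatrix,
    labels: Union[QuadrantLabeling, np.ndarray],
    variables: Optional[Sequence[str]] = None,
    fdr: bool = False,
) -> pd.DataFrame:
    """Kruskal-Wallis test per variable against the group labels.

    With ``fdr=True`` a Benjamini-Hochberg adjusted p-value column is added
    and significance tiers are recomputed from it.
    """
    groups = labels.classes if isinstance(labels, QuadrantLabeling) else np.asarray(labels)
    if variables is None:
        variables = list(matrix.variable_names)
    sub = matrix.select(list(variables))
    rows = []
    for j, name in enumerate(sub.variable_names):
        res = kruskal_wallis(sub.values[:, j], groups, variable=name)
        rows.append(
            {
                "variable": name,
                "h": res.h,
                "df": res.df,
                "pvalue": res.pvalue,
                "tier": res.tier,
            }
        )
    df = pd.DataFrame(rows)
    if fdr:
        df["pvalue_bh"] = benjamini_hochberg(df["pvalue"].to_numpy())
        df["tier"] = [significance_tier(p) for p in df["pvalue_bh"]]
    return df


def group_summaries(
    matrix: FeatureMatrix,
    labels: Union[QuadrantLabeling, np.ndarray],
    variables: Sequence[str],
) -> pd.DataFrame:
    """Per variable x group: min, Q1, median, Q3, max and n (box-plot stats).

    Quartiles use linear interpolation of the empirical CDF.
    """
    groups = labels.classes if isinstance(labels, QuadrantLabeling) else np.asarray(labels)
    sub = matrix.select(list(variables))
    rows = []
    for j, name in enumerate(sub.variable_names):
        col = sub.values[:, j]
        for lab in np.unique(groups):
            vals = col[groups == lab]
            q1, med, q3 = np.quantile(vals, [0.25, 0.5, 0.75])
            rows.append(
                {
                    "variable": name,
                    "class": lab,
                    "min": vals.min(),
                    "q1": q1,
                    "median": med,
                    "q3": q3,
                    "max": vals.max(),
                    "n": vals.size,
                }
            )
    return pd.DataFrame(rows)
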