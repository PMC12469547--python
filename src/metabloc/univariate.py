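"""Per-metabolite two-group screen: Mann-Whitney U, BH-FDR, log2 fold change.

The univariate stage tests each metabolite for a distributional shift
between the two groups (Mann-Whitney U, two-sided), adjusts p-values by
Benjamini-Hochberg step-up, and quantifies effect direction and size by
the log2 ratio of group means on PQN-normalized (pre-autoscaling)
intensities, with the Term group as reference.  A metabolite is called
significant when p_adj < alpha AND |log2FC| > fc_threshold (the volcano
rule).
"""

from __future__ import annotations

from itertools import combinations
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .containers import FeatureMatrix

__all__ = [
    "mann_whitney_u",
    "bh_fdr",
    "log2_fold_change",
    "univariate_table",
    "volcano_table",
    "VolcanoCounts",
]

#: Exact null enumeration is used when the pooled sample size is at most
#: this and there are no ties; otherwise the tie-corrected normal
#: approximation with continuity correction applies.
EXACT_N_MAX = 12


def _exact_two_sided_p(u_obs: float, n1: int, n2: int) -> float:
    """Exact two-sided p by enumerating all C(n1+n2, n1) rank assignments."""
    ranks = range(1, n1 + n2 + 1)
    nm = n1 * n2
    us = np.array(
        [sum(c) - n1 * (n1 + 1) / 2 for c in combinations(ranks, n1)], dtype=float
    )
    u_small = min(u_obs, nm - u_obs)
    p = (np.sum(us <= u_small) + np.sum(us >= nm - u_small)) / len(us)
    return float(min(1.0, p))


def mann_whitney_u(group_a, group_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Returns (U, p) where U is the statistic of ``group_a`` computed from
    midrank rank sums.  Exact enumeration when n_a + n_b <= 12 and the
    pooled data has no ties; else normal approximation with tie
    correction and continuity correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups need at least one observation")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)
    nm = n1 * n2

    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = np.any(tie_counts > 1)

    if n1 + n2 <= EXACT_N_MAX and not has_ties:
        return u1, _exact_two_sided_p(u1, n1, n2)

    n = n1 + n2
    tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1))
    sigma2 = nm / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return u1, 1.0  # all observations tied
    mu = nm / 2.0
    diff = u1 - mu
    cc = 0.5 * np.sign(diff)
    z = (diff - cc) / np.sqrt(sigma2) if diff != 0 else 0.0
    p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
    return u1, p


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order preserved)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adjusted = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(adjusted[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def log2_fold_change(
    matrix: FeatureMatrix,
    groups: pd.Series,
    reference: str = "Term",
    estimator: str = "mean",
) -> pd.Series:
    """Per-metabolite log2 ratio of group centers, reference in the denominator.

    Positive values mean elevated in the non-reference (Prem) group.
    Requires PQN-normalized, strictly positive, non-autoscaled values
    (autoscaled data can be negative, making the ratio undefined).
    """
    if matrix.state == "autoscaled":
        raise ValueError("log2 fold change requires pre-autoscaling intensities")
    groups = groups.loc[matrix.data.index]
    levels = set(pd.unique(groups))
    if reference not in levels:
        raise ValueError(f"reference group {reference!r} not present in labels {levels}")
    (other,) = levels - {reference}
    center = {"mean": lambda d: d.mean(axis=0), "median": lambda d: d.median(axis=0)}[
        estimator
    ]
    ref_mean = center(matrix.data.loc[groups == reference])
    other_mean = center(matrix.data.loc[groups == other])
    if (ref_mean <= 0).any() or (other_mean <= 0).any():
        raise ValueError("non-positive group center; fold change undefined")
    out = np.log2(other_mean / ref_mean)
    out.name = "log2fc"
    return out


def univariate_table(
    matrix: FeatureMatrix,
    groups: pd.Series,
    alpha: float = 0.05,
    fc_threshold: float = 0.6,
    reference: str = "Term",
    estimator: str = "mean",
) -> pd.DataFrame:
    """Full univariate screen: U, p, BH-adjusted p, log2FC, significance."""
    groups = groups.loc[matrix.data.index]
    levels = set(pd.unique(groups))
    if reference not in levels or len(levels) != 2:
        raise ValueError("need exactly two groups including the reference")
    (other,) = levels - {reference}
    x_other = matrix.data.loc[groups == other]
    x_ref = matrix.data.loc[groups == reference]

    stats_rows = [
        mann_whitney_u(x_other[m].to_numpy(), x_ref[m].to_numpy())
        for m in matrix.data.columns
    ]
    u = np.array([r[0] for r in stats_rows])
    p = np.array([r[1] for r in stats_rows])
    table = pd.DataFrame(
        {
            "U": u,
            "p": p,
            "p_adj": bh_fdr(p),
            "log2fc": log2_fold_change(matrix, groups, reference, estimator),
        },
        index=matrix.data.columns,
    )
    table["significant"] = (table["p_adj"] < alpha) & (table["log2fc"].abs() > fc_threshold)
    return table


class VolcanoCounts(NamedTuple):
    up: int
    down: int
    ns: int


def volcano_table(
    table: pd.DataFrame, alpha: float = 0.05, fc_threshold: float = 0.6
) -> tuple[pd.DataFrame, VolcanoCounts]:
    """Classify metabolites as up / down / ns by the volcano rule.

    ``up`` means elevated in the non-reference (Prem) group.
    """
    out = table.copy()
    sig = (out["p_adj"] < alpha) & (out["log2fc"].abs() > fc_threshold)
    out["significant"] = sig
    direction = np.where(~sig, "ns", np.where(out["log2fc"] > 0, "up", "down"))
    out["direction"] = direction
    counts = VolcanoCounts(
        up=int((out["direction"] == "up").sum()),
        down=int((out["direction"] == "down").sum()),
        ns=int((out["direction"] == "ns").sum()),
    )
    return out, counts
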