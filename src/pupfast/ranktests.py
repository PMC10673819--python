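"""Nonparametric battery: Kruskal–Wallis, Dunn post hoc, chi-square.

The replicate unit for the proportion comparisons is the sampling event
(one rookery on one date), so group sizes are small and ties are common;
the implementations here therefore expose the mid-rank tie correction,
report group mean ranks, and offer an exact permutation p-value for small
pooled samples where the chi-square approximation is poor.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RankTestResult",
    "kruskal_wallis",
    "dunn_bonferroni",
    "sex_ratio_chisq",
]


@dataclass(frozen=True)
class RankTestResult:
    """Kruskal–Wallis test result with rank diagnostics."""

    statistic: float  # tie-corrected H
    df: int
    pvalue: float
    mean_ranks: tuple[float, ...]
    tie_correction: float  # C in H = H_raw / C; 1 means no ties
    method: str  # "asymptotic" or "exact"


def _kw_statistic(groups: list[np.ndarray]) -> tuple[float, tuple[float, ...], float]:
    """Tie-corrected H, per-group mean ranks and the tie factor C."""
    pooled = np.concatenate(groups)
    n = pooled.size
    ranks = stats.rankdata(pooled)  # mid-ranks
    splits = np.cumsum([g.size for g in groups])[:-1]
    group_ranks = np.split(ranks, splits)
    mean_ranks = tuple(float(r.mean()) for r in group_ranks)

    h_raw = 12.0 / (n * (n + 1)) * sum(
        r.sum() ** 2 / r.size for r in group_ranks
    ) - 3.0 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    c = 1.0 - float(np.sum(counts**3 - counts)) / (n**3 - n) if n > 1 else 1.0
    if c == 0.0:  # every observation identical
        return 0.0, mean_ranks, 0.0
    return max(h_raw / c, 0.0), mean_ranks, c


def kruskal_wallis(
    groups: Sequence[Sequence[float]], p_method: str = "asymptotic"
) -> RankTestResult:
    """Kruskal–Wallis one-way ANOVA on ranks with mid-rank tie correction.

    ``p_method="asymptotic"`` uses the chi-square approximation with
    df = k − 1; ``"exact"`` enumerates every distinct assignment of the
    pooled observations to the group sizes (feasible for pooled n ≤ 10)
    and reports the exact permutation tail probability P(H* ≥ H).

    All observations identical gives H = 0 and p = 1 by convention.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2:
        raise ValueError("need at least two groups")
    if any(a.size == 0 for a in arrs):
        raise ValueError("every group needs at least one observation")

    h, mean_ranks, c = _kw_statistic(arrs)
    df = len(arrs) - 1
    if c == 0.0:
        return RankTestResult(0.0, df, 1.0, mean_ranks, 0.0, p_method)

    if p_method == "asymptotic":
        p = float(stats.chi2.sf(h, df))
    elif p_method == "exact":
        pooled = np.concatenate(arrs)
        n = pooled.size
        if n > 10:
            raise ValueError("exact enumeration supported only for pooled n <= 10")
        sizes = [a.size for a in arrs]
        count = 0
        total = 0
        idx = list(range(n))
        # enumerate distinct assignments (unordered within groups)
        for assignment in _assignments(idx, sizes):
            perm_groups = [pooled[list(ix)] for ix in assignment]
            h_perm, _, _ = _kw_statistic(perm_groups)
            total += 1
            if h_perm >= h - 1e-12:
                count += 1
        p = count / total
    else:
        raise ValueError(f"unknown p_method {p_method!r}")
    return RankTestResult(float(h), df, p, mean_ranks, c, p_method)


def _assignments(indices: list[int], sizes: list[int]):
    """Yield all ways to split ``indices`` into ordered groups of ``sizes``."""
    if len(sizes) == 1:
        yield (tuple(indices),)
        return
    first, rest_sizes = sizes[0], sizes[1:]
    for combo in itertools.combinations(indices, first):
        remaining = [i for i in indices if i not in combo]
        for rest in _assignments(remaining, rest_sizes):
            yield (combo,) + rest


def dunn_bonferroni(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Dunn's post-hoc z tests for all group pairs, Bonferroni-adjusted.

    z for a pair is the difference in mean ranks over its pooled-rank
    standard error with tie correction; adjusted p = min(1, m · p_raw)
    where m counts all pairwise comparisons.  Empty groups are dropped
    with a warning.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if labels is None:
        labels = [str(i) for i in range(len(arrs))]
    keep = [i for i, a in enumerate(arrs) if a.size > 0]
    if len(keep) < len(arrs):
        warnings.warn("dropping empty group(s) from Dunn test")
    arrs = [arrs[i] for i in keep]
    labels = [labels[i] for i in keep]
    if len(arrs) < 2:
        raise ValueError("need at least two nonempty groups")

    pooled = np.concatenate(arrs)
    n = pooled.size
    ranks = stats.rankdata(pooled)
    splits = np.cumsum([a.size for a in arrs])[:-1]
    group_ranks = np.split(ranks, splits)
    mean_ranks = [r.mean() for r in group_ranks]
    sizes = [a.size for a in arrs]

    _, counts = np.unique(pooled, return_counts=True)
    tie_sum = float(np.sum(counts**3 - counts))
    var_base = n * (n + 1) / 12.0 - tie_sum / (12.0 * (n - 1))

    pairs = list(itertools.combinations(range(len(arrs)), 2))
    m = len(pairs)
    rows = []
    for i, j in pairs:
        se = math.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p_raw = 2.0 * stats.norm.sf(abs(z))
        rows.append(
            {
                "group_i": labels[i],
                "group_j": labels[j],
                "z": z,
                "p_raw": p_raw,
                "p_adj": min(1.0, m * p_raw),
            }
        )
    return pd.DataFrame(rows)


def sex_ratio_chisq(
    records: pd.DataFrame,
    category_col: str = "fasting_category",
    sex_col: str = "sex",
    subpop_col: str = "subpopulation",
) -> pd.DataFrame:
    """Chi-square tests of sex distribution within fasting categories.

    For each fasting category, a Pearson chi-square (no continuity
    correction) of the subpopulation × sex contingency table; plus one
    overall goodness-of-fit test of the pooled M:F count against 50:50.
    Rows carry a low-expected-count warning flag when any expected cell
    is below 5.
    """
    df = records[records[sex_col].isin(["M", "F"])]
    rows = []
    for cat, grp in df.groupby(category_col, sort=True):
        tab = pd.crosstab(grp[subpop_col], grp[sex_col])
        if tab.shape[0] < 2 or tab.shape[1] < 2:
            rows.append(
                {"scope": cat, "chi2": np.nan, "df": 0, "pvalue": np.nan,
                 "n": int(tab.to_numpy().sum()), "low_expected": False}
            )
            continue
        chi2, p, dof, expected = stats.chi2_contingency(tab.to_numpy(), correction=False)
        rows.append(
            {
                "scope": cat,
                "chi2": float(chi2),
                "df": int(dof),
                "pvalue": float(p),
                "n": int(tab.to_numpy().sum()),
                "low_expected": bool((expected < 5).any()),
            }
        )

    n_m = int((df[sex_col] == "M").sum())
    n_f = int((df[sex_col] == "F").sum())
    if n_m + n_f > 0:
        chi2, p = stats.chisquare([n_m, n_f])
        rows.append(
            {
                "scope": "overall_vs_50_50",
                "chi2": float(chi2),
                "df": 1,
                "pvalue": float(p),
                "n": n_m + n_f,
                "low_expected": (n_m + n_f) < 10,
            }
        )
    return pd.DataFrame(rows)
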