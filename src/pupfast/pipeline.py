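"""End-to-end orchestration: raw records → full results bundle.

The bundle is a dictionary of tidy tables (written as CSVs by the CLI):
``rejections``, ``july19``, ``proportions``, ``unclassified``,
``ranktests``, ``dunn``, ``model_coefficients``, ``marginal_means``,
``contrasts``, ``chisq`` and ``selection_trace``.  Every input row is
either analysed or logged with a reason; reruns on the same input are
byte-identical (the only randomness, the Tukey adjustment's Monte Carlo,
runs at a fixed seed).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .classify import FastingThresholds, classify_dataframe
from .cohort import (
    PHASE_CATEGORIES,
    category_proportions,
    expectation_match,
    filter_min_group,
    july19_check,
)
from .model import FastingDurationModel
from .ranktests import dunn_bonferroni, kruskal_wallis, sex_ratio_chisq

__all__ = ["run_analysis", "REQUIRED_COLUMNS"]

REQUIRED_COLUMNS = ("rookery", "subpopulation", "capture_date", "sex",
                    "bun_mmol_l", "bhba_mmol_l")


def run_analysis(
    records: pd.DataFrame,
    thresholds: FastingThresholds | None = None,
    min_group_n: int = 5,
    alpha: float = 0.05,
    seed: int = 20160719,
) -> dict[str, pd.DataFrame]:
    """Run QC-classified records through the full statistical battery."""
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise KeyError(f"input schema missing columns: {missing}")
    if thresholds is None:
        thresholds = FastingThresholds.default()

    bundle: dict[str, pd.DataFrame] = {}

    classified = classify_dataframe(records, thresholds)
    kept, rejections = filter_min_group(classified, min_n=min_group_n)
    bundle["rejections"] = rejections
    bundle["july19"] = july19_check(kept, alpha=alpha)

    props = category_proportions(kept)
    bundle["proportions"] = props.table
    bundle["unclassified"] = props.unclassified

    # per-category Kruskal-Wallis across subpopulations on event proportions
    kw_rows, dunn_frames = [], []
    for cat in PHASE_CATEGORIES:
        ev = props.event_proportions[props.event_proportions["category"] == cat]
        groups, labels = [], []
        for sub, g in ev.groupby("subpopulation", sort=True):
            groups.append(g["proportion"].to_numpy())
            labels.append(str(sub))
        if len(groups) < 2:
            continue
        res = kruskal_wallis(groups)
        kw_rows.append(
            {"category": cat, "H": res.statistic, "df": res.df,
             "pvalue": res.pvalue, "n_groups": len(groups)}
        )
        if res.pvalue < alpha:
            dn = dunn_bonferroni(groups, labels)
            dn.insert(0, "category", cat)
            dunn_frames.append(dn)
    bundle["ranktests"] = pd.DataFrame(kw_rows)
    bundle["dunn"] = (
        pd.concat(dunn_frames, ignore_index=True)
        if dunn_frames
        else pd.DataFrame(columns=["category", "group_i", "group_j", "z", "p_raw", "p_adj"])
    )

    if "note_tags" in kept.columns:
        bundle["expectations"] = expectation_match(kept)

    model = FastingDurationModel.from_dataframe(kept)
    top, trace = model.fit_selected(alpha=alpha)
    bundle["selection_trace"] = trace
    wald = top.wald_tests().reset_index(names="term")
    bundle["model_coefficients"] = wald

    try:
        bundle["marginal_means"] = top.marginal_means("subpopulation")
    except ValueError:
        bundle["marginal_means"] = pd.DataFrame(
            columns=["subpopulation", "estimate", "ci_low", "ci_high"]
        )
    try:
        bundle["contrasts"] = top.tukey_contrasts("subpopulation", seed=seed)
    except ValueError:
        bundle["contrasts"] = pd.DataFrame(
            columns=["level_i", "level_j", "estimate", "se", "z", "p_adj", "significant"]
        )

    bundle["chisq"] = sex_ratio_chisq(kept)
    bundle["classified"] = kept
    return bundle
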