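"""Cohort assembly: selection rules, geography, proportions, validation.

The analysis unit for proportion comparisons is the sampling event (one
rookery on one date); events with fewer than five pups are dropped so
event-level proportions are meaningful.  Rookeries map to one of 12
subpopulations in four broad regions across the North Pacific, with the
Distinct Population Segment (DPS) boundary at 144°W longitude.  Before
pups captured late in the season enter the analysis, each subpopulation's
recently-fed proportion is compared before vs after July 19 — the date
when dam foraging trips have been observed to lengthen — so that a
seasonal attendance shift cannot masquerade as a geographic difference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .classify import FastingCategory
from .ranktests import kruskal_wallis

__all__ = [
    "load_rookery_map",
    "assign_subpopulation",
    "filter_min_group",
    "july19_check",
    "category_proportions",
    "ProportionTable",
    "expectation_match",
    "DEFAULT_EXPECTED_MAP",
]

#: the four phase categories whose proportions sum to one per group
PHASE_CATEGORIES = (
    FastingCategory.FED_I.value,
    FastingCategory.II.value,
    FastingCategory.II_III.value,
    FastingCategory.III.value,
)

_DPS_WEST_BOUNDARY_DEG = -144.0  # Cape Suckling; east of this is the eastern DPS


def load_rookery_map(path=None) -> pd.DataFrame:
    """Load the versioned rookery → subpopulation/region mapping.

    The shipped CSV carries rookery name, subpopulation, region and an
    approximate longitude (degrees, east positive); the DPS column is
    derived from the 144°W rule so the mapping cannot contradict it.
    """
    if path is None:
        ref = resources.files("pupfast").joinpath("data/rookeries.csv")
        with resources.as_file(ref) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    lon = df["longitude_deg"].astype(float)
    df["dps"] = np.where((lon > _DPS_WEST_BOUNDARY_DEG) & (lon < 0), "eastern", "western")
    return df


def assign_subpopulation(
    rookery: str, mapping: pd.DataFrame | None = None
) -> tuple[str, str, str]:
    """Look up (subpopulation, region, dps) for a rookery name."""
    if mapping is None:
        mapping = load_rookery_map()
    rows = mapping[mapping["rookery"] == rookery]
    if rows.empty:
        raise KeyError(
            f"unknown rookery {rookery!r}; valid: {sorted(mapping['rookery'])}"
        )
    r = rows.iloc[0]
    return str(r["subpopulation"]), str(r["region"]), str(r["dps"])


def filter_min_group(
    records: pd.DataFrame,
    min_n: int = 5,
    key: tuple[str, ...] = ("rookery", "capture_date"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop sampling events with fewer than ``min_n`` pups.

    Returns the surviving records and a rejection log listing each removed
    event with its pup count.  Idempotent: filtering a filtered table
    changes nothing.
    """
    missing = [k for k in key if k not in records.columns]
    if missing:
        raise KeyError(f"missing key columns: {missing}")
    if records.empty:
        return records.copy(), pd.DataFrame(columns=[*key, "n", "reason"])

    sizes = records.groupby(list(key), sort=False).transform("size")
    keep = sizes.iloc[:, 0] >= min_n if isinstance(sizes, pd.DataFrame) else sizes >= min_n
    rejected = (
        records.loc[~keep]
        .groupby(list(key), sort=False)
        .size()
        .reset_index(name="n")
    )
    rejected["reason"] = f"fewer than {min_n} pups in sampling event"
    return records.loc[keep].copy(), rejected


def _event_category_proportions(
    records: pd.DataFrame,
    group_col: str,
    category_col: str,
    replicate_unit: str = "event",
) -> pd.DataFrame:
    """Per-replicate proportions of each phase among classified pups.

    The replicate unit is either the sampling event (rookery × date,
    default) or the rookery-year (``replicate_unit="rookery_year"``).
    """
    classified = records[records[category_col].isin(PHASE_CATEGORIES)]
    if replicate_unit == "event":
        unit = classified["capture_date"].astype(str)
    elif replicate_unit == "rookery_year":
        unit = pd.to_datetime(classified["capture_date"]).dt.year.astype(str)
    else:
        raise ValueError(f"unknown replicate_unit {replicate_unit!r}")
    rows = []
    for (grp, rook, date), ev in classified.groupby(
        [classified[group_col], classified["rookery"], unit], sort=True
    ):
        n = len(ev)
        for cat in PHASE_CATEGORIES:
            rows.append(
                {
                    group_col: grp,
                    "rookery": rook,
                    "capture_date": date,
                    "category": cat,
                    "n_event": n,
                    "proportion": (ev[category_col] == cat).sum() / n,
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ProportionTable:
    """Per-group fasting-category composition.

    ``table`` has one row per (group, category) with counts and the
    proportion among the four phase categories (these sum to 1 within a
    group; Unclassified pups are counted separately in
    ``unclassified``).  ``event_proportions`` keeps the per-sampling-event
    proportions that serve as replicate units for the rank tests.
    """

    table: pd.DataFrame
    unclassified: pd.DataFrame
    event_proportions: pd.DataFrame


def category_proportions(
    records: pd.DataFrame,
    by: str = "subpopulation",
    category_col: str = "fasting_category",
    replicate_unit: str = "event",
) -> ProportionTable:
    """Tabulate fasting-category counts and proportions per group.

    ``replicate_unit`` selects the units retained for the rank tests:
    sampling events (rookery × date, default) or rookery-years.
    """
    if category_col not in records.columns:
        raise KeyError(f"records lack a {category_col!r} column")

    classified = records[records[category_col].isin(PHASE_CATEGORIES)]
    rows = []
    for grp, g in classified.groupby(by, sort=True):
        n_grp = len(g)
        for cat in PHASE_CATEGORIES:
            n_cat = int((g[category_col] == cat).sum())
            rows.append(
                {by: grp, "category": cat, "n": n_cat, "proportion": n_cat / n_grp}
            )
    table = pd.DataFrame(rows)

    uncls = (
        records[records[category_col] == FastingCategory.UNCLASSIFIED.value]
        .groupby(by, sort=True)
        .size()
        .reset_index(name="n_unclassified")
    )
    total = records.groupby(by, sort=True).size().reset_index(name="n_total")
    uncls = total.merge(uncls, on=by, how="left").fillna({"n_unclassified": 0})
    uncls["n_unclassified"] = uncls["n_unclassified"].astype(int)
    uncls["fraction_of_total"] = uncls["n_unclassified"] / uncls["n_total"]

    events = _event_category_proportions(records, by, category_col, replicate_unit)
    return ProportionTable(table=table, unclassified=uncls, event_proportions=events)


def july19_check(
    records: pd.DataFrame,
    by: str = "subpopulation",
    category_col: str = "fasting_category",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Compare recently-fed proportions before vs after July 19 per group.

    "Post" means captured strictly after July 19 of any year (i.e. July 20
    onward).  The comparison is a Kruskal–Wallis test on sampling-event
    Fed–I proportions; groups with no post-period (or no pre-period)
    events are marked not applicable.
    """
    dates = pd.to_datetime(records["capture_date"])
    post = (dates.dt.month > 7) | ((dates.dt.month == 7) & (dates.dt.day > 19))
    records = records.assign(_post=post.values)

    rows = []
    for grp, g in records.groupby(by, sort=True):
        ev = _event_category_proportions(g, by, category_col)
        ev = ev[ev["category"] == FastingCategory.FED_I.value]
        ev_dates = pd.to_datetime(ev["capture_date"])
        ev_post = (ev_dates.dt.month > 7) | (
            (ev_dates.dt.month == 7) & (ev_dates.dt.day > 19)
        )
        pre_props = ev.loc[~ev_post.values, "proportion"].to_numpy()
        post_props = ev.loc[ev_post.values, "proportion"].to_numpy()
        row = {
            by: grp,
            "n_pre_events": pre_props.size,
            "n_post_events": post_props.size,
            "pre_fed1_proportion": pre_props.mean() if pre_props.size else np.nan,
            "post_fed1_proportion": post_props.mean() if post_props.size else np.nan,
        }
        if pre_props.size == 0 or post_props.size == 0:
            row.update({"H": np.nan, "df": np.nan, "pvalue": np.nan,
                        "applicable": False, "flagged": False})
        else:
            res = kruskal_wallis([pre_props, post_props])
            row.update(
                {
                    "H": res.statistic,
                    "df": res.df,
                    "pvalue": res.pvalue,
                    "applicable": True,
                    "flagged": bool(res.pvalue < alpha),
                }
            )
        rows.append(row)
    return pd.DataFrame(rows)


#: expected categories per field-note tag for the a-priori validation
DEFAULT_EXPECTED_MAP: dict[str, frozenset[str]] = {
    "neonate": frozenset({FastingCategory.FED_I.value}),
    "milk_in_stomach": frozenset({FastingCategory.FED_I.value}),
    "emaciated_starveling_orphaned": frozenset(
        {FastingCategory.II_III.value, FastingCategory.III.value}
    ),
    # skinny/thin is a subjective field impression: no a-priori expectation
    "skinny_thin": frozenset(),
}

_VIDEO_FED1_MAX_HOURS = 16.0  # last seen with dam < 16 h ago -> expect Fed-I


def expectation_match(
    records: pd.DataFrame,
    expected_map: dict[str, frozenset[str]] | None = None,
    category_col: str = "fasting_category",
    tags_col: str = "note_tags",
) -> pd.DataFrame:
    """Score classifier outcomes against a-priori field-note expectations.

    ``note_tags`` is a semicolon-joined tag string per pup.  The
    ``video_dam_hours:<h>`` tag carries the hours since the pup was last
    seen with its dam; under 16 h the expectation is Fed–I (longer
    intervals carry no sharp expectation and are skipped).  Tags with an
    empty expectation set are excluded with a warning.
    """
    if expected_map is None:
        expected_map = DEFAULT_EXPECTED_MAP

    stats: dict[str, list[int]] = {}
    for tags_str, cat in zip(records[tags_col].fillna(""), records[category_col]):
        if not tags_str or pd.isna(cat):
            continue
        for tag in str(tags_str).split(";"):
            tag = tag.strip()
            if not tag:
                continue
            if tag.startswith("video_dam_hours:"):
                hours = float(tag.split(":", 1)[1])
                if hours >= _VIDEO_FED1_MAX_HOURS:
                    continue
                name, expected = "video_dam_hours<16", {FastingCategory.FED_I.value}
            elif tag in expected_map:
                expected = expected_map[tag]
                if not expected:
                    warnings.warn(f"tag {tag!r} has an empty expectation set; excluded")
                    continue
                name = tag
            else:
                continue
            n, match = stats.setdefault(name, [0, 0])
            stats[name][0] = n + 1
            stats[name][1] = match + (1 if cat in expected else 0)

    rows = [
        {"tag": tag, "n": n, "matches": m, "match_proportion": m / n if n else np.nan}
        for tag, (n, m) in sorted(stats.items())
    ]
    return pd.DataFrame(rows)
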