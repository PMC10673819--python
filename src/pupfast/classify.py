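"""Fasting-phase classification from plasma metabolites.

Free-ranging otariid pups fast on the rookery while their dam forages at
sea.  Over a fast the predominant endogenous fuel changes, and with it two
cheap plasma markers: blood urea nitrogen (BUN, protein catabolism) and
beta-hydroxybutyrate (β-HBA, lipid catabolism / ketosis).  A pup's position
on the fasting continuum is assigned from the joint (BUN, β-HBA) reading:

======================  ===========================  ====================
category                BUN (mmol/L)                 β-HBA (mmol/L)
======================  ===========================  ====================
Recently Fed–Phase I    elevated (dietary protein)   very low (< elevated)
Phase II                lowered (protein sparing)    elevated (ketotic)
Phase II–III            rising again                 still elevated
Phase III               high (protein catabolism)    back near baseline
Unclassified            high                         elevated (both high)
======================  ===========================  ====================

Numeric cutpoints live in a config file (``data/thresholds.yaml``) so that
the decision table is auditable and replaceable; nothing here hard-wires a
concentration.  Boundary convention: lower bounds inclusive, upper bounds
exclusive, stated in the config and checked exhaustively by the test grid.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from importlib import resources
from typing import Union

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "FastingCategory",
    "DurationClass",
    "FastingThresholds",
    "classify_fasting_phase",
    "duration_class",
    "body_condition_index",
    "classify_dataframe",
]


class FastingCategory(str, enum.Enum):
    """Discrete position on the fasting continuum."""

    FED_I = "Fed-I"
    II = "II"
    II_III = "II-III"
    III = "III"
    UNCLASSIFIED = "Unclassified"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class DurationClass(str, enum.Enum):
    """Binary collapse of the fasting categories for the duration model."""

    SHORT = "Short"
    LONG = "Long"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: categories collapsed to a Short (recently fed / early) fast
SHORT_CATEGORIES = frozenset({FastingCategory.FED_I, FastingCategory.II})


@dataclass(frozen=True)
class FastingThresholds:
    """Cutpoints (mmol/L) that induce the fasting-phase decision regions.

    Parameters
    ----------
    bhba_elevated
        β-HBA at or above this value counts as "elevated" (ketotic).  The
        default 0.3 mmol/L is the screening threshold used in the field.
    bun_phase2_max
        With elevated β-HBA, BUN below this value indicates protein-sparing
        Phase II; at or above it, protein catabolism has resumed (II–III).
    bun_high
        BUN at or above this value counts as "high": with low β-HBA this is
        Phase III; with elevated β-HBA the combination does not occur on
        the fasting continuum and the pup is Unclassified.
    """

    bhba_elevated: float = 0.3
    bun_phase2_max: float = 5.0
    bun_high: float = 9.0

    def __post_init__(self) -> None:
        for name in ("bhba_elevated", "bun_phase2_max", "bun_high"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be positive and finite, got {v}")
        if not self.bun_phase2_max < self.bun_high:
            raise ValueError("bun_phase2_max must be below bun_high")

    @classmethod
    def from_yaml(cls, path) -> "FastingThresholds":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls(**{k: float(v) for k, v in raw.items()})

    @classmethod
    def default(cls) -> "FastingThresholds":
        """Package defaults, read from the shipped ``thresholds.yaml``."""
        ref = resources.files("pupfast").joinpath("data/thresholds.yaml")
        with resources.as_file(ref) as path:
            return cls.from_yaml(path)


def classify_fasting_phase(
    bun: float, bhba: float, thresholds: FastingThresholds | None = None
) -> FastingCategory:
    """Assign the fasting category for one (BUN, β-HBA) pair.

    Total and deterministic on the nonnegative quadrant: exactly one
    category is returned for every valid input (grid-tested exhaustively).
    Lower bounds are inclusive, upper bounds exclusive.

    Raises
    ------
    ValueError
        If either concentration is missing, negative or non-finite.
    """
    if thresholds is None:
        thresholds = FastingThresholds.default()
    for name, v in (("bun", bun), ("bhba", bhba)):
        if v is None or not np.isfinite(v):
            raise ValueError(f"{name} missing or non-finite: {v!r}")
        if v < 0:
            raise ValueError(f"{name} must be nonnegative, got {v}")

    ketotic = bhba >= thresholds.bhba_elevated
    if not ketotic:
        if bun < thresholds.bun_high:
            return FastingCategory.FED_I
        return FastingCategory.III
    if bun < thresholds.bun_phase2_max:
        return FastingCategory.II
    if bun < thresholds.bun_high:
        return FastingCategory.II_III
    return FastingCategory.UNCLASSIFIED


def duration_class(category: Union[FastingCategory, str]) -> DurationClass:
    """Collapse a fasting category to Short or Long.

    Fed–I and II pups are Short; II–III, III and Unclassified pups are
    Long (unclassifiable pups show both markers elevated, i.e. they are
    deep into the fast, and are merged into Long for the duration model
    only — category tables report them separately).
    """
    category = FastingCategory(category)
    return DurationClass.SHORT if category in SHORT_CATEGORIES else DurationClass.LONG


# body condition index: mass over a linear function of standard length
_BCI_INTERCEPT = -63.88
_BCI_SLOPE = 0.8966


def body_condition_index(mass_kg: float, length_cm: float) -> float:
    """Body condition index: mass / (−63.88 + 0.8966·standard length).

    A sexually dimorphic species needs a condition index rather than raw
    morphometrics; this divides observed mass by a length-predicted mass.
    The denominator turns nonpositive below ~71.25 cm, outside the index's
    domain of validity.

    Raises
    ------
    ValueError
        If mass is nonpositive or the length-predicted denominator is
        nonpositive (pup too short for the index).
    """
    if not mass_kg > 0:
        raise ValueError(f"mass must be positive, got {mass_kg}")
    denom = _BCI_INTERCEPT + _BCI_SLOPE * length_cm
    if not denom > 0:
        raise ValueError(
            f"length {length_cm} cm outside index domain (denominator {denom:.3f} <= 0)"
        )
    return mass_kg / denom


def classify_dataframe(
    df: pd.DataFrame,
    thresholds: FastingThresholds | None = None,
    bun_col: str = "bun_mmol_l",
    bhba_col: str = "bhba_mmol_l",
) -> pd.DataFrame:
    """Append ``fasting_category``, ``duration_class`` and ``bci`` columns.

    Rows with a missing metabolite get NA in the derived columns; pups
    whose length lies outside the condition-index domain get NA for
    ``bci``.  The input frame is not modified.
    """
    if thresholds is None:
        thresholds = FastingThresholds.default()
    missing = [c for c in (bun_col, bhba_col) if c not in df.columns]
    if missing:
        raise KeyError(f"missing metabolite columns: {missing}")

    out = df.copy()
    cats: list[object] = []
    for bun, bhba in zip(out[bun_col], out[bhba_col]):
        if pd.isna(bun) or pd.isna(bhba):
            cats.append(pd.NA)
        else:
            cats.append(classify_fasting_phase(float(bun), float(bhba), thresholds).value)
    out["fasting_category"] = cats
    out["duration_class"] = [
        pd.NA if pd.isna(c) else duration_class(c).value for c in cats
    ]

    if {"mass_kg", "length_cm"}.issubset(out.columns):
        bci = []
        for m, l in zip(out["mass_kg"], out["length_cm"]):
            try:
                bci.append(body_condition_index(float(m), float(l)))
            except (ValueError, TypeError):
                bci.append(np.nan)
        out["bci"] = bci
    return out
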