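"""Plate-assay reduction and QC for plasma metabolite measurements.

Raw endpoint-assay responses become accepted concentrations through four
gates, mirroring standard wet-lab practice for these kits:

1. a four-parameter logistic (4PL) standard curve fitted to known
   standards and inverted to map responses to concentrations;
2. a technical-replicate precision gate (CV ≤ 10%), with one repeat assay
   permitted before exclusion;
3. a two-stage β-HBA screen: a handheld ketometer (0.1 mmol/L resolution)
   splits samples around the 0.3 mmol/L phase boundary, and readings in
   the 0.2–0.4 mmol/L band are sent to the biochemical assay for better
   precision (~0.01 mmol/L) around that threshold;
4. hemolysis exclusion: moderately/severely hemolysed plasma is dropped.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "StandardCurve",
    "PlateMeasurement",
    "KetometerDecision",
    "fit_standard_curve",
    "replicate_cv",
    "ketometer_screen",
    "accept_sample",
    "AcceptedSample",
    "ExcludedSample",
    "process_plate",
]


@dataclass(frozen=True)
class StandardCurve:
    """4PL standard curve y = d + (a − d) / (1 + (x/c)^b).

    ``a`` is the zero-concentration response asymptote, ``d`` the
    infinite-concentration asymptote, ``c`` the inflection concentration
    and ``b`` the slope factor.  Inversion is defined only strictly
    between the asymptotes; ``valid_range`` records the concentration span
    of the standards used for the fit.
    """

    a: float
    b: float
    c: float
    d: float
    valid_range: tuple[float, float]
    residual_norm: float = float("nan")

    def evaluate(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.d + (self.a - self.d) / (1.0 + (x / self.c) ** self.b)

    def invert(self, y) -> np.ndarray:
        """Concentration(s) producing response ``y``.

        Raises
        ------
        ValueError
            If ``y`` lies outside the open interval between the asymptotes.
        """
        y = np.asarray(y, dtype=float)
        lo, hi = sorted((self.a, self.d))
        if np.any(y <= lo) or np.any(y >= hi):
            raise ValueError(
                f"response outside invertible range ({lo:.6g}, {hi:.6g})"
            )
        return self.c * ((self.a - self.d) / (y - self.d) - 1.0) ** (1.0 / self.b)


@dataclass(frozen=True)
class PlateMeasurement:
    """Replicate responses for one sample/analyte on a plate."""

    sample_id: str
    analyte: str  # "BUN" or "BHBA"
    replicate_responses: Sequence[float]
    hemolysis: str = "none"  # none | slight | moderate | severe
    repeat_responses: Sequence[float] | None = None  # one permitted repeat assay

    def __post_init__(self) -> None:
        if len(self.replicate_responses) < 1:
            raise ValueError("at least one replicate response required")
        if not np.all(np.isfinite(self.replicate_responses)):
            raise ValueError("replicate responses must be finite")
        if self.hemolysis not in ("none", "slight", "moderate", "severe"):
            raise ValueError(f"unknown hemolysis grade {self.hemolysis!r}")


class KetometerDecision(str, enum.Enum):
    BELOW = "below"
    ABOVE = "above"
    RETEST = "retest_by_assay"


def fit_standard_curve(
    known_concs: Sequence[float], responses: Sequence[float]
) -> StandardCurve:
    """Least-squares 4PL fit of responses against known standards.

    Bounded nonlinear least squares with log-spaced initialisations of the
    inflection ``c`` across the standard range; the best of the multistart
    fits is kept.  Standards must be monotone in concentration.
    """
    x = np.asarray(known_concs, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 standards for a 4PL fit")
    if np.any(x <= 0):
        raise ValueError("standard concentrations must be positive")
    order = np.argsort(x)
    x, y = x[order], y[order]
    dy = np.diff(y)
    if not (np.all(dy > 0) or np.all(dy < 0)):
        raise ValueError("standards are not monotone in response; cannot fit 4PL")

    span = y.max() - y.min()
    if span == 0:
        raise ValueError("flat responses; cannot fit 4PL")

    def residuals(p):
        a, b, c, d = p
        return d + (a - d) / (1.0 + (x / c) ** b) - y

    best = None
    pad = 0.5 * span
    lo_bounds = [y.min() - 10 * span, 1e-6, x.min() / 100.0, y.min() - 10 * span]
    hi_bounds = [y.max() + 10 * span, 100.0, x.max() * 100.0, y.max() + 10 * span]
    a0 = y[0] + (pad if y[0] > y[-1] else -pad) * 0.0
    d0 = y[-1]
    for c0 in np.geomspace(x.min(), x.max(), 5):
        try:
            sol = optimize.least_squares(
                residuals,
                x0=[a0, 1.0, c0, d0],
                bounds=(lo_bounds, hi_bounds),
                method="trf",
            )
        except ValueError:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not best.success:
        raise ValueError("4PL fit failed to converge")
    a, b, c, d = best.x
    return StandardCurve(
        a=float(a),
        b=float(b),
        c=float(c),
        d=float(d),
        valid_range=(float(x.min()), float(x.max())),
        residual_norm=float(np.linalg.norm(best.fun)),
    )


def replicate_cv(responses: Sequence[float]) -> tuple[float, bool]:
    """Percent coefficient of variation of technical replicates and the gate.

    CV = 100 · s / mean with the sample (n−1) standard deviation; the gate
    passes at CV ≤ 10% (boundary inclusive).  A single replicate has an
    undefined CV and passes with cv = nan.
    """
    arr = np.asarray(responses, dtype=float)
    if arr.size == 0:
        raise ValueError("no replicates")
    mean = arr.mean()
    if mean <= 0:
        raise ValueError(f"replicate mean must be positive, got {mean}")
    if arr.size == 1:
        return float("nan"), True
    cv = 100.0 * arr.std(ddof=1) / mean
    return float(cv), bool(cv <= 10.0)


def ketometer_screen(
    value_mmol_l: float,
    threshold: float = 0.3,
    retest_band: tuple[float, float] = (0.2, 0.4),
) -> KetometerDecision:
    """Two-stage β-HBA screen on a handheld ketometer reading.

    Readings within the closed retest band (default 0.2–0.4 mmol/L) go to
    the biochemical assay for precision around the 0.3 mmol/L phase
    boundary; everything else is decided directly against the threshold.
    """
    if value_mmol_l < 0:
        raise ValueError("ketometer reading must be nonnegative")
    lo, hi = retest_band
    if lo <= value_mmol_l <= hi:
        return KetometerDecision.RETEST
    return KetometerDecision.BELOW if value_mmol_l < threshold else KetometerDecision.ABOVE


@dataclass(frozen=True)
class AcceptedSample:
    sample_id: str
    analyte: str
    concentration_mmol_l: float
    cv_percent: float


@dataclass(frozen=True)
class ExcludedSample:
    sample_id: str
    analyte: str
    reason: str  # hemolysis | cv | range


def accept_sample(
    plate: PlateMeasurement, curve: StandardCurve
) -> AcceptedSample | ExcludedSample:
    """Reduce one plate measurement to an accepted concentration or exclusion.

    Order of gates: hemolysis (moderate/severe excluded outright), then
    the replicate-CV gate on the first-pass responses with one permitted
    repeat assay, then curve inversion (responses outside the invertible
    interval exclude the sample with reason ``range``).  The accepted
    value is the mean of the replicate concentrations.
    """
    if plate.hemolysis in ("moderate", "severe"):
        return ExcludedSample(plate.sample_id, plate.analyte, "hemolysis")

    responses = plate.replicate_responses
    cv, ok = replicate_cv(responses)
    if not ok:
        if plate.repeat_responses is None:
            return ExcludedSample(plate.sample_id, plate.analyte, "cv")
        responses = plate.repeat_responses
        cv, ok = replicate_cv(responses)
        if not ok:
            return ExcludedSample(plate.sample_id, plate.analyte, "cv")

    try:
        concs = curve.invert(responses)
    except ValueError:
        return ExcludedSample(plate.sample_id, plate.analyte, "range")
    return AcceptedSample(
        plate.sample_id, plate.analyte, float(np.mean(concs)), cv
    )


def process_plate(
    df: pd.DataFrame, curves: dict[str, StandardCurve]
) -> pd.DataFrame:
    """QC-reduce a long-format plate table to per-sample decisions.

    Expects columns ``sample_id``, ``analyte``, ``replicate``, ``response``
    and ``hemolysis``; an optional ``pass`` column (1 = first pass, 2 =
    repeat assay) feeds the one-repeat rule.  Returns one row per
    (sample, analyte) with ``status``, ``reason``, ``concentration_mmol_l``
    and ``cv_percent``.
    """
    required = {"sample_id", "analyte", "replicate", "response", "hemolysis"}
    missing = required - set(df.columns)
    if missing:
        raise KeyError(f"plate table missing columns: {sorted(missing)}")

    rows = []
    for (sid, analyte), grp in df.groupby(["sample_id", "analyte"], sort=True):
        passes = grp["pass"] if "pass" in grp.columns else pd.Series(1, index=grp.index)
        first = grp.loc[passes == 1, "response"].tolist()
        repeat = grp.loc[passes == 2, "response"].tolist() or None
        plate = PlateMeasurement(
            sample_id=str(sid),
            analyte=str(analyte),
            replicate_responses=first,
            hemolysis=str(grp["hemolysis"].iloc[0]),
            repeat_responses=repeat,
        )
        result = accept_sample(plate, curves[str(analyte)])
        if isinstance(result, AcceptedSample):
            rows.append(
                {
                    "sample_id": sid,
                    "analyte": analyte,
                    "status": "accepted",
                    "reason": "",
                    "concentration_mmol_l": result.concentration_mmol_l,
                    "cv_percent": result.cv_percent,
                }
            )
        else:
            rows.append(
                {
                    "sample_id": sid,
                    "analyte": analyte,
                    "status": "excluded",
                    "reason": result.reason,
                    "concentration_mmol_l": math.nan,
                    "cv_percent": math.nan,
                }
            )
    return pd.DataFrame(rows)
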