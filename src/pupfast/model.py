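"""Binomial model of fasting duration (Short vs Long).

The scientific question is geographic: after accounting for body
condition, sex and sampling timing, do subpopulations differ in the
probability that a pup is caught in a Long-duration fast?  The model is a
binomial GLM with a logit link,

    logit P(Long) = β₀ + f(BCI, subpopulation, sex, post-July-19, …),

reduced from a global fixed-effects-plus-interactions form by backward
selection with likelihood-ratio tests.  Reporting goes through
sex-corrected marginal means per subpopulation (equal sex weights on the
linear-predictor scale, back-transformed) and all-pairs Tukey contrasts
with a single-step max-|z| adjustment evaluated by Monte Carlo from the
joint normal distribution of the contrast estimates.

Usage follows the Model/Results idiom::

    model = FastingDurationModel.from_dataframe(records)
    res = model.fit()                       # global model
    top, trace = model.fit_selected()       # backward-selected model
    top.marginal_means()                    # per-subpopulation P(Long), CI
    top.tukey_contrasts()                   # 66 pairwise contrasts
"""

from __future__ import annotations

import itertools
import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import patsy
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .classify import DurationClass

__all__ = [
    "FastingDurationModel",
    "FastingDurationResults",
    "fit_binomial",
    "backward_select",
    "marginal_means",
    "tukey_contrasts",
]

_DEFAULT_MAIN_TERMS = ("bci", "C(subpopulation)", "C(sex)", "post_july19")


def _components(term: str) -> frozenset[str]:
    return frozenset(t.strip() for t in term.split(":"))


def _term_variables(terms) -> list[str]:
    """Raw column names referenced by a list of formula terms."""
    names: list[str] = []
    for term in terms:
        for comp in term.split(":"):
            comp = comp.strip()
            m = re.fullmatch(r"C\((\w+)\)", comp)
            names.append(m.group(1) if m else comp)
    seen: list[str] = []
    for n in names:
        if n not in seen:
            seen.append(n)
    return seen


class FastingDurationModel:
    """Binomial (logit) model of Short/Long fasting duration.

    Parameters
    ----------
    data
        Prepared complete-case frame containing the binary ``long``
        response (1 = Long fast) and every referenced covariate.
    terms
        Formula terms of the linear predictor (the intercept is implicit).
    """

    def __init__(self, data: pd.DataFrame, terms: tuple[str, ...]):
        self.terms = tuple(terms)
        self.variables = _term_variables(self.terms)
        missing = [v for v in self.variables + ["long"] if v not in data.columns]
        if missing:
            raise KeyError(f"model data missing columns: {missing}")
        self.data = data.reset_index(drop=True)

    # -- construction -------------------------------------------------

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        terms: tuple[str, ...] | None = None,
        include_interactions: bool = True,
    ) -> "FastingDurationModel":
        """Build the model frame from classified pup records.

        Derives the binary ``long`` response from ``duration_class``, the
        body condition index ``bci`` from mass/length when absent, and
        the ``post_july19`` timing factor from the capture date.  Pups of
        unknown sex and incomplete cases are dropped.  The default global
        model has the four main effects and all two-way interactions.
        """
        from .classify import body_condition_index

        d = df.copy()
        if "duration_class" not in d.columns:
            raise KeyError("records need a 'duration_class' column (classify first)")
        d = d[d["duration_class"].notna()]
        d["long"] = (d["duration_class"] == DurationClass.LONG.value).astype(int)

        if "bci" not in d.columns and {"mass_kg", "length_cm"}.issubset(d.columns):
            bci = []
            for m, l in zip(d["mass_kg"], d["length_cm"]):
                try:
                    bci.append(body_condition_index(float(m), float(l)))
                except (ValueError, TypeError):
                    bci.append(np.nan)
            d["bci"] = bci
        if "post_july19" not in d.columns and "capture_date" in d.columns:
            dates = pd.to_datetime(d["capture_date"])
            d["post_july19"] = (
                (dates.dt.month > 7) | ((dates.dt.month == 7) & (dates.dt.day > 19))
            ).astype(int)

        if terms is None:
            terms = tuple(t for t in _DEFAULT_MAIN_TERMS if _term_variables([t])[0] in d)
            if include_interactions:
                terms = terms + tuple(
                    f"{a}:{b}" for a, b in itertools.combinations(terms, 2)
                )

        variables = _term_variables(terms)
        if "sex" in variables:
            d = d[d["sex"].isin(["M", "F"])]
        d = d.dropna(subset=[v for v in variables if v in d.columns] + ["long"])
        return cls(d, tuple(terms))

    # -- fitting ------------------------------------------------------

    @property
    def formula(self) -> str:
        rhs = " + ".join(self.terms) if self.terms else "1"
        return f"long ~ {rhs}"

    def fit(
        self, terms: tuple[str, ...] | None = None, warn_separation: bool = True
    ) -> "FastingDurationResults":
        terms = self.terms if terms is None else tuple(terms)
        rhs = " + ".join(terms) if terms else "1"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # perfect-separation warnings surfaced below
            res = smf.glm(
                f"long ~ {rhs}", data=self.data, family=sm.families.Binomial()
            ).fit()
            fitted = np.asarray(res.fittedvalues)
            params = np.asarray(res.params)
            res.llf, res.deviance, res.cov_params()  # force lazy evals here
        separation = bool(
            np.any(fitted < 1e-8)
            or np.any(fitted > 1 - 1e-8)
            or np.any(np.abs(params) > 15)
        )
        if separation and warn_separation:
            warnings.warn(
                "possible separation in the binomial fit (a cell may be all-Short "
                "or all-Long); consider a penalized fit or coarser factors"
            )
        return FastingDurationResults(self, terms, res, separation)

    def fit_selected(
        self, alpha: float = 0.05
    ) -> tuple["FastingDurationResults", pd.DataFrame]:
        """Backward selection by likelihood-ratio tests at ``alpha``.

        Interactions are removable before the main effects they contain
        (marginality).  At each step the least-significant removable term
        (largest LRT p ≥ alpha) is dropped; the trace records every step.
        """
        terms = list(self.terms)
        trace_rows = []
        current = self.fit(tuple(terms), warn_separation=False)
        while terms:
            removable = [
                t
                for t in terms
                if not any(
                    t != s and _components(t) < _components(s) for s in terms
                )
            ]
            best = None
            for t in removable:
                reduced_terms = tuple(s for s in terms if s != t)
                reduced = self.fit(reduced_terms, warn_separation=False)
                lr, df, p = current.lrt(reduced)
                if best is None or p > best[3]:
                    best = (t, reduced, df, p, lr)
            if best is None or best[3] < alpha:
                break
            t, reduced, df, p, lr = best
            trace_rows.append(
                {"removed_term": t, "lr_stat": lr, "df": df, "pvalue": p,
                 "remaining": " + ".join(s for s in terms if s != t) or "1"}
            )
            terms.remove(t)
            current = reduced
        trace = pd.DataFrame(
            trace_rows, columns=["removed_term", "lr_stat", "df", "pvalue", "remaining"]
        )
        return current, trace


class FastingDurationResults:
    """Fitted binomial duration model: estimates, uncertainty, reporting."""

    def __init__(self, model, terms, sm_results, separation_flag):
        self.model = model
        self.terms = tuple(terms)
        self._res = sm_results
        self.separation_flag = separation_flag

    # thin statsmodels pass-throughs
    @property
    def params(self) -> pd.Series:
        return self._res.params

    @property
    def bse(self) -> pd.Series:
        return self._res.bse

    @property
    def llf(self) -> float:
        return float(self._res.llf)

    @property
    def deviance(self) -> float:
        return float(self._res.deviance)

    @property
    def converged(self) -> bool:
        return bool(self._res.converged)

    def cov_params(self) -> pd.DataFrame:
        return self._res.cov_params()

    def wald_tests(self) -> pd.DataFrame:
        """Per-coefficient Wald z statistics and p-values."""
        z = self._res.params / self._res.bse
        return pd.DataFrame(
            {"coef": self._res.params, "se": self._res.bse, "z": z,
             "pvalue": 2 * stats.norm.sf(np.abs(z))}
        )

    def summary(self):
        return self._res.summary()

    def lrt(self, reduced: "FastingDurationResults") -> tuple[float, int, float]:
        """Likelihood-ratio test of this fit against a nested reduction."""
        lr = 2.0 * (self.llf - reduced.llf)
        df = int(self._rank() - reduced._rank())
        if df <= 0:
            return max(lr, 0.0), 0, 1.0
        return max(lr, 0.0), df, float(stats.chi2.sf(max(lr, 0.0), df))

    def _rank(self) -> int:
        return int(np.linalg.matrix_rank(self._res.model.exog))

    # -- reference grid ------------------------------------------------

    def _grid_row_design(self, assignments: dict) -> np.ndarray:
        """Design-matrix row for one covariate assignment; others at
        reference values (numeric mean, categorical mode)."""
        data = self.model.data
        row = {}
        for v in _term_variables(self.terms):
            if v in assignments:
                row[v] = assignments[v]
            elif pd.api.types.is_numeric_dtype(data[v]):
                row[v] = data[v].mean()
            else:
                row[v] = data[v].mode().iloc[0]
        frame = pd.DataFrame([row]) if row else pd.DataFrame(index=[0])
        (mat,) = patsy.build_design_matrices(
            [self._res.model.data.design_info], frame
        )
        return np.asarray(mat)[0]

    def _averaged_rows(
        self, factor: str, average_over: tuple[str, ...], weights: str
    ) -> tuple[list[str], np.ndarray]:
        """Sex(etc.)-averaged design rows, one per factor level."""
        data = self.model.data
        if factor not in _term_variables(self.terms):
            raise ValueError(f"factor {factor!r} is not in the fitted model")
        levels = sorted(data[factor].unique())
        over = [v for v in average_over if v in _term_variables(self.terms)]

        combos: list[tuple[dict, float]] = [({}, 1.0)]
        for v in over:
            vals = sorted(data[v].unique())
            if weights == "equal":
                w = {val: 1.0 / len(vals) for val in vals}
            elif weights == "observed":
                freq = data[v].value_counts(normalize=True)
                w = {val: float(freq[val]) for val in vals}
            else:
                raise ValueError(f"unknown weights {weights!r}")
            combos = [
                ({**assign, v: val}, wt * w[val])
                for assign, wt in combos
                for val in vals
            ]

        rows = []
        for level in levels:
            x = np.zeros(len(self._res.params))
            for assign, wt in combos:
                x = x + wt * self._grid_row_design({factor: level, **assign})
            rows.append(x)
        return [str(l) for l in levels], np.vstack(rows)

    def marginal_means(
        self,
        factor: str = "subpopulation",
        average_over: tuple[str, ...] = ("sex",),
        weights: str = "equal",
        conf_level: float = 0.95,
    ) -> pd.DataFrame:
        """Model-based P(Long) per factor level, averaged over sex.

        Averaging happens on the linear-predictor scale at equal (or
        observed) weights; the CI is the Wald interval on the linear
        predictor back-transformed through the inverse logit, so both the
        estimate and its bounds live in (0, 1).
        """
        levels, rows = self._averaged_rows(factor, average_over, weights)
        beta = self._res.params.to_numpy()
        cov = self.cov_params().to_numpy()
        eta = rows @ beta
        se = np.sqrt(np.einsum("ij,jk,ik->i", rows, cov, rows))
        zcrit = stats.norm.ppf(0.5 + conf_level / 2.0)
        from scipy.special import expit

        return pd.DataFrame(
            {
                factor: levels,
                "estimate": expit(eta),
                "ci_low": expit(eta - zcrit * se),
                "ci_high": expit(eta + zcrit * se),
                "eta": eta,
                "se_eta": se,
            }
        )

    def tukey_contrasts(
        self,
        factor: str = "subpopulation",
        average_over: tuple[str, ...] = ("sex",),
        alpha: float = 0.05,
        seed: int = 20160719,
        nsamples: int = 40000,
    ) -> pd.DataFrame:
        """All-pairs contrasts of factor levels, single-step adjusted.

        Contrasts are differences of the averaged linear predictors
        (log-odds scale).  The family-wise adjustment references each |z|
        against the Monte-Carlo distribution of the maximum |z| over the
        whole family, drawn from the joint normal of the contrast
        estimates at a fixed seed (the single-step max-|z| method).  With
        a single contrast the exact two-sided normal p is returned.
        """
        levels, rows = self._averaged_rows(factor, average_over, "equal")
        beta = self._res.params.to_numpy()
        cov = self.cov_params().to_numpy()
        pairs = list(itertools.combinations(range(len(levels)), 2))

        cmat = np.array([rows[i] - rows[j] for i, j in pairs])
        est = cmat @ beta
        se = np.sqrt(np.einsum("ij,jk,ik->i", cmat, cov, cmat))
        se = np.where(se > 0, se, np.nan)
        z = est / se

        if len(pairs) == 1:
            p_adj = np.array([2.0 * stats.norm.sf(abs(z[0]))])
        else:
            rng = np.random.default_rng(seed)
            # contrast covariance -> correlated z draws via eigendecomposition
            ccov = cmat @ cov @ cmat.T
            d = np.sqrt(np.diag(ccov))
            corr = ccov / np.outer(d, d)
            vals, vecs = np.linalg.eigh(corr)
            vals = np.clip(vals, 0.0, None)
            root = vecs * np.sqrt(vals)
            draws = rng.standard_normal((nsamples, len(vals))) @ root.T
            maxabs = np.abs(draws).max(axis=1)
            p_adj = np.array([(maxabs >= abs(zk)).mean() for zk in z])

        return pd.DataFrame(
            {
                "level_i": [levels[i] for i, _ in pairs],
                "level_j": [levels[j] for _, j in pairs],
                "estimate": est,
                "se": se,
                "z": z,
                "p_adj": p_adj,
                "significant": p_adj < alpha,
            }
        )


# -- functional conveniences mirroring the object API -------------------


def fit_binomial(records: pd.DataFrame, terms=None, **kwargs) -> FastingDurationResults:
    """Fit the binomial duration model on classified records."""
    return FastingDurationModel.from_dataframe(records, terms=terms, **kwargs).fit()


def backward_select(
    fit: FastingDurationResults, alpha: float = 0.05
) -> tuple[FastingDurationResults, pd.DataFrame]:
    """Backward-select from a fitted global model (LRT at ``alpha``)."""
    model = FastingDurationModel(fit.model.data, fit.terms)
    return model.fit_selected(alpha=alpha)


def marginal_means(fit: FastingDurationResults, **kwargs) -> pd.DataFrame:
    return fit.marginal_means(**kwargs)


def tukey_contrasts(fit: FastingDurationResults, **kwargs) -> pd.DataFrame:
    return fit.tukey_contrasts(**kwargs)
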