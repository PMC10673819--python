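"""Binomial duration model: closed forms, selection, marginal means, Tukey."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from pupfast import FastingDurationModel, backward_select, fit_binomial


def _frame(long, **cols):
    df = pd.DataFrame({"duration_class": np.where(long, "Long", "Short")})
    for k, v in cols.items():
        df[k] = v
    return df


class TestClosedForms:
    def test_intercept_only_equals_logit_of_rate(self):
        long = np.r_[np.ones(60), np.zeros(40)].astype(bool)
        model = FastingDurationModel.from_dataframe(_frame(long), terms=())
        res = model.fit()
        assert res.params["Intercept"] == pytest.approx(logit(0.6), abs=1e-6)

    def test_two_group_log_odds_exact(self):
        # 2x2 contingency: group A 30/70 Long, group B 10/90 Long
        long = np.r_[np.ones(30), np.zeros(70), np.ones(10), np.zeros(90)].astype(bool)
        sub = ["A"] * 100 + ["B"] * 100
        res = FastingDurationModel.from_dataframe(
            _frame(long, subpopulation=sub), terms=("C(subpopulation)",)
        ).fit()
        assert res.params["Intercept"] == pytest.approx(logit(0.3), abs=1e-6)
        assert res.params["C(subpopulation)[T.B]"] == pytest.approx(
            logit(0.1) - logit(0.3), abs=1e-6
        )

    def test_saturated_two_factor_reproduces_cell_log_odds(self):
        cells = {("A", "M"): 0.2, ("A", "F"): 0.4, ("B", "M"): 0.1, ("B", "F"): 0.5}
        frames = []
        for (sub, sex), p in cells.items():
            k = int(p * 100)
            frames.append(
                _frame(np.r_[np.ones(k), np.zeros(100 - k)].astype(bool),
                       subpopulation=sub, sex=sex)
            )
        df = pd.concat(frames, ignore_index=True)
        res = FastingDurationModel.from_dataframe(
            df, terms=("C(subpopulation)", "C(sex)", "C(subpopulation):C(sex)")
        ).fit()
        beta = res.params
        eta = {
            ("A", "F"): beta["Intercept"],
            ("A", "M"): beta["Intercept"] + beta["C(sex)[T.M]"],
            ("B", "F"): beta["Intercept"] + beta["C(subpopulation)[T.B]"],
            ("B", "M"): beta["Intercept"] + beta["C(subpopulation)[T.B]"]
            + beta["C(sex)[T.M]"] + beta["C(subpopulation)[T.B]:C(sex)[T.M]"],
        }
        for cell, p in cells.items():
            assert eta[cell] == pytest.approx(logit(p), abs=1e-6)

    def test_sex_effect_recovery_at_large_n(self):
        rng = np.random.default_rng(8)
        n = 5000
        sex = np.where(rng.random(n) < 0.5, "F", "M")
        eta = -1.0 + 0.4 * (sex == "F")
        long = rng.random(n) < expit(eta)
        res = FastingDurationModel.from_dataframe(
            _frame(long, sex=sex), terms=("C(sex)",)
        ).fit()
        assert res.params["C(sex)[T.M]"] == pytest.approx(-0.4, abs=0.1)


class TestBackwardSelection:
    def test_null_terms_reduce_to_intercept_mostly(self):
        """With no true effects, selection ends intercept-only in most reps."""
        rng = np.random.default_rng(17)
        reps, intercept_only = 60, 0
        for _ in range(reps):
            n = 400
            df = _frame(
                rng.random(n) < 0.3,
                sex=np.where(rng.random(n) < 0.5, "F", "M"),
                bci=rng.normal(1.1, 0.1, n),
            )
            model = FastingDurationModel.from_dataframe(df, terms=("C(sex)", "bci"))
            top, _ = model.fit_selected()
            intercept_only += len(top.terms) == 0
        assert intercept_only / reps > 0.85  # ≈ (1-alpha)² with null LRTs

    def test_true_effects_retained_nulls_dropped(self):
        rng = np.random.default_rng(4)
        n = 5000
        sex = np.where(rng.random(n) < 0.5, "F", "M")
        sub = rng.choice(["A", "B", "C"], n)
        bci = rng.normal(1.1, 0.1, n)
        eta = -1.5 + 0.5 * (sex == "F") + 1.0 * (sub == "C")
        df = _frame(rng.random(n) < expit(eta), sex=sex, subpopulation=sub, bci=bci)
        model = FastingDurationModel.from_dataframe(
            df, terms=("C(sex)", "C(subpopulation)", "bci")
        )
        top, trace = model.fit_selected()
        assert set(top.terms) == {"C(sex)", "C(subpopulation)"}
        assert list(trace["removed_term"]) == ["bci"]

    def test_marginality_interactions_removed_first(self):
        rng = np.random.default_rng(5)
        n = 2000
        sex = np.where(rng.random(n) < 0.5, "F", "M")
        sub = rng.choice(["A", "B"], n)
        eta = -1.0 + 0.8 * (sex == "F") + 0.8 * (sub == "B")  # no interaction
        df = _frame(rng.random(n) < expit(eta), sex=sex, subpopulation=sub)
        model = FastingDurationModel.from_dataframe(
            df, terms=("C(sex)", "C(subpopulation)", "C(sex):C(subpopulation)")
        )
        top, trace = model.fit_selected()
        assert "C(sex):C(subpopulation)" not in top.terms
        assert {"C(sex)", "C(subpopulation)"} <= set(top.terms)
        if len(trace):
            assert trace["removed_term"].iloc[0] == "C(sex):C(subpopulation)"

    def test_no_removable_term_below_alpha_unchanged(self):
        rng = np.random.default_rng(6)
        n = 4000
        sex = np.where(rng.random(n) < 0.5, "F", "M")
        eta = -1.0 + 1.5 * (sex == "F")
        df = _frame(rng.random(n) < expit(eta), sex=sex)
        model = FastingDurationModel.from_dataframe(df, terms=("C(sex)",))
        top, trace = model.fit_selected()
        assert top.terms == ("C(sex)",) and trace.empty

    def test_functional_wrapper_matches_method(self):
        rng = np.random.default_rng(9)
        n = 500
        df = _frame(rng.random(n) < 0.3, sex=np.where(rng.random(n) < 0.5, "F", "M"))
        fit = fit_binomial(df, terms=("C(sex)",))
        top, _ = backward_select(fit)
        assert isinstance(top.terms, tuple)


class TestMarginalMeans:
    def test_intercept_only_mean_equals_observed_proportion(self):
        long = np.r_[np.ones(30), np.zeros(70)].astype(bool)
        res = FastingDurationModel.from_dataframe(_frame(long), terms=()).fit()
        assert expit(res.params["Intercept"]) == pytest.approx(0.3, abs=1e-9)

    def test_balanced_no_sex_effect_equals_raw_proportions(self):
        """With sex balanced and uninformative, marginal means are the raw
        per-subpopulation Long proportions."""
        frames = []
        for sub, p in (("A", 0.2), ("B", 0.4)):
            for sex in ("M", "F"):
                k = int(p * 50)
                frames.append(
                    _frame(np.r_[np.ones(k), np.zeros(50 - k)].astype(bool),
                           subpopulation=sub, sex=sex)
                )
        df = pd.concat(frames, ignore_index=True)
        res = FastingDurationModel.from_dataframe(
            df, terms=("C(subpopulation)", "C(sex)")
        ).fit()
        mm = res.marginal_means(factor="subpopulation", average_over=("sex",))
        assert mm.set_index("subpopulation")["estimate"]["A"] == pytest.approx(0.2, abs=1e-6)
        assert mm.set_index("subpopulation")["estimate"]["B"] == pytest.approx(0.4, abs=1e-6)
        assert ((mm["ci_low"] >= 0) & (mm["ci_high"] <= 1)).all()
        assert (mm["ci_low"] < mm["estimate"]).all() and (mm["estimate"] < mm["ci_high"]).all()

    def test_factor_absent_from_model_errors(self):
        long = np.r_[np.ones(20), np.zeros(20)].astype(bool)
        res = FastingDurationModel.from_dataframe(
            _frame(long, subpopulation=["A", "B"] * 20), terms=()
        ).fit()
        with pytest.raises(ValueError, match="not in the fitted model"):
            res.marginal_means(factor="subpopulation")

    def test_observed_weights_option(self):
        rng = np.random.default_rng(3)
        n = 600
        sex = np.where(rng.random(n) < 0.7, "M", "F")
        sub = rng.choice(["A", "B"], n)
        df = _frame(rng.random(n) < 0.3, sex=sex, subpopulation=sub)
        res = FastingDurationModel.from_dataframe(
            df, terms=("C(subpopulation)", "C(sex)")
        ).fit()
        eq = res.marginal_means(weights="equal")
        ob = res.marginal_means(weights="observed")
        assert not np.allclose(eq["estimate"], ob["estimate"])


class TestTukeyContrasts:
    def test_two_levels_adjusted_equals_unadjusted(self):
        long = np.r_[np.ones(30), np.zeros(70), np.ones(15), np.zeros(85)].astype(bool)
        df = _frame(long, subpopulation=["A"] * 100 + ["B"] * 100)
        res = FastingDurationModel.from_dataframe(df, terms=("C(subpopulation)",)).fit()
        con = res.tukey_contrasts("subpopulation")
        assert len(con) == 1
        from scipy import stats
        assert con["p_adj"].iloc[0] == pytest.approx(
            2 * stats.norm.sf(abs(con["z"].iloc[0])), abs=1e-12
        )

    def test_twelve_levels_yield_66_contrasts(self, classified):
        res = FastingDurationModel.from_dataframe(
            classified, terms=("C(subpopulation)", "C(sex)")
        ).fit()
        con = res.tukey_contrasts("subpopulation", nsamples=5000)
        assert len(con) == 66
        from scipy import stats
        raw = 2 * stats.norm.sf(np.abs(con["z"]))
        # single-step family-wise adjustment can only increase p (up to MC error)
        assert (con["p_adj"] >= raw - 0.02).all()

    def test_adjustment_is_deterministic_given_seed(self, classified):
        res = FastingDurationModel.from_dataframe(
            classified, terms=("C(subpopulation)", "C(sex)")
        ).fit()
        a = res.tukey_contrasts("subpopulation", seed=1, nsamples=5000)
        b = res.tukey_contrasts("subpopulation", seed=1, nsamples=5000)
        pd.testing.assert_frame_equal(a, b)

    def test_elevated_level_dominates_significant_set(self):
        rng = np.random.default_rng(12)
        subs = [f"S{k}" for k in range(6)]
        frames = []
        for sub in subs:
            p = 0.45 if sub == "S3" else 0.10
            n = 300
            frames.append(
                _frame(rng.random(n) < p, subpopulation=np.repeat(sub, n))
            )
        df = pd.concat(frames, ignore_index=True)
        res = FastingDurationModel.from_dataframe(df, terms=("C(subpopulation)",)).fit()
        con = res.tukey_contrasts("subpopulation", nsamples=20000)
        sig = con[con["significant"]]
        assert len(sig) > 0
        assert ((sig["level_i"] == "S3") | (sig["level_j"] == "S3")).all()


class TestDiagnostics:
    def test_separation_warned_and_flagged(self):
        long = np.r_[np.ones(30), np.zeros(30)].astype(bool)
        df = _frame(long, subpopulation=["A"] * 30 + ["B"] * 30)
        model = FastingDurationModel.from_dataframe(df, terms=("C(subpopulation)",))
        with pytest.warns(UserWarning, match="separation"):
            res = model.fit()
        assert res.separation_flag

    def test_summary_and_wald(self, classified):
        res = FastingDurationModel.from_dataframe(
            classified, terms=("C(subpopulation)", "C(sex)")
        ).fit()
        assert "C(sex)[T.M]" in res.wald_tests().index
        assert res.converged
        text = str(res.summary())
        assert "long" in text

    def test_missing_duration_column_raises(self):
        with pytest.raises(KeyError, match="duration_class"):
            FastingDurationModel.from_dataframe(pd.DataFrame({"x": [1]}))
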