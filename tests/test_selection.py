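"""Sub-cohort construction, logistic screening, and the intersection rule."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from helpers import irls_logistic
from t2drisk.selection import (
    SeparationError,
    build_sub_cohorts,
    fit_multivariate_logit,
    run_selection,
    select_risk_variables,
)


def _toy_cohort(ages, sexes):
    return pd.DataFrame({"age": ages, "sex": sexes})


class TestSubCohorts:
    def test_partition_identities(self):
        rng = np.random.default_rng(0)
        df = _toy_cohort(rng.uniform(20, 80, 100), rng.integers(0, 2, 100))
        subs = build_sub_cohorts(df)
        assert len(subs["male"]) + len(subs["female"]) == len(subs["all"])
        assert len(subs["under_50"]) + len(subs["over_50"]) == len(subs["all"])

    def test_degenerate_all_young_men(self):
        df = _toy_cohort([25.0] * 10, [1] * 10)
        subs = build_sub_cohorts(df)
        assert len(subs["male"]) == 10 and len(subs["female"]) == 0
        assert len(subs["under_50"]) == 10

    def test_age_exactly_50_goes_to_upper_stratum(self):
        df = _toy_cohort([49.9, 50.0, 50.1], [1, 1, 1])
        subs = build_sub_cohorts(df)
        assert subs["over_50"]["age"].tolist() == [50.0, 50.1]
        assert subs["under_50"]["age"].tolist() == [49.9]

    def test_missing_columns_raise(self):
        with pytest.raises(KeyError):
            build_sub_cohorts(pd.DataFrame({"age": [30.0]}))


class TestLogit:
    def test_parameter_recovery_within_wald_error(self):
        rng = np.random.default_rng(1)
        n = 20000
        x = rng.standard_normal(n)
        y = (rng.random(n) < expit(-3 + 0.8 * x)).astype(int)
        tab = fit_multivariate_logit(pd.DataFrame({"x": x, "diabetes": y}), ["x"])
        assert abs(tab.loc["const", "beta"] + 3) < 2 * tab.loc["const", "se"]
        assert abs(tab.loc["x", "beta"] - 0.8) < 2 * tab.loc["x", "se"]

    def test_intercept_only_fit_at_half_prevalence(self):
        y = np.array([0, 1] * 2500)
        x = np.arange(5000) % 7 / 7.0  # non-constant but uninformative
        tab = fit_multivariate_logit(pd.DataFrame({"x": x, "diabetes": y}), ["x"])
        assert abs(tab.loc["const", "beta"]) < 0.2

    @pytest.mark.parametrize("ds_seed", range(5))
    def test_estimates_match_independent_irls_solver(self, ds_seed):
        rng = np.random.default_rng(100 + ds_seed)
        n = 400
        x1, x2 = rng.standard_normal(n), rng.standard_normal(n)
        y = (rng.random(n) < expit(0.3 + 0.7 * x1 - 0.4 * x2)).astype(int)
        df = pd.DataFrame({"a": x1, "b": x2, "diabetes": y})
        tab = fit_multivariate_logit(df, ["a", "b"])
        ref = irls_logistic(np.column_stack([np.ones(n), x1, x2]), y)
        np.testing.assert_allclose(
            tab["beta"].to_numpy(), ref, atol=1e-6, rtol=0)

    def test_constant_variable_rejected(self):
        df = pd.DataFrame({"x": [1.0] * 10, "diabetes": [0, 1] * 5})
        with pytest.raises(ValueError, match="'x'"):
            fit_multivariate_logit(df, ["x"])

    def test_perfect_separation_names_the_variable(self):
        df = pd.DataFrame({
            "sep": np.r_[np.zeros(20), np.ones(20)],
            "noise": np.random.default_rng(2).standard_normal(40),
            "diabetes": np.r_[np.zeros(20, int), np.ones(20, int)],
        })
        with pytest.raises(SeparationError, match="sep"):
            fit_multivariate_logit(df, ["sep", "noise"])


class TestSelectionRule:
    def _lr_table(self, pvals):
        return pd.DataFrame({
            "beta": 0.1, "se": 0.05, "p": pd.Series(pvals),
        })

    def test_plain_intersection(self):
        freq = {"AGE": 9, "BMI": 8, "TG": 7}
        lr = self._lr_table({"BMI": 0.01, "TG": 0.02, "SBP": 0.03})
        rep = select_risk_variables(freq, lr, frequency_threshold=4,
                                    overrides={}, exclusions={})
        assert rep.final_variables == ["BMI", "TG"]

    def test_override_keeps_failed_variable_and_flags_it(self):
        freq = {"HDL": 9, "BMI": 8}
        lr = self._lr_table({"HDL": 0.30, "BMI": 0.01})
        rep = select_risk_variables(
            freq, lr, overrides={"hdl_up": "protective factor"}, exclusions={})
        # HDL fails the p-value screen but the override retains it
        assert "hdl_up" in rep.final_variables
        assert "hdl_up" in rep.overrides
        assert "HDL" not in rep.final_variables  # not intersected, not overridden

    def test_override_never_removes_intersected_variable(self):
        freq = {"BMI": 8, "TG": 6}
        lr = self._lr_table({"BMI": 0.01, "TG": 0.01})
        base = select_risk_variables(freq, lr, overrides={}, exclusions={})
        extended = select_risk_variables(
            freq, lr, overrides={"psh": "family history"}, exclusions={})
        assert set(base.final_variables) <= set(extended.final_variables)

    def test_empty_intersection_returns_empty_selection(self):
        freq = {"AGE": 9}
        lr = self._lr_table({"BMI": 0.01})
        rep = select_risk_variables(freq, lr, overrides={}, exclusions={})
        assert rep.final_variables == []

    def test_frequency_threshold_is_strict(self):
        freq = {"A": 4, "B": 5}
        lr = self._lr_table({"A": 0.01, "B": 0.01})
        rep = select_risk_variables(freq, lr, frequency_threshold=4,
                                    overrides={}, exclusions={})
        assert rep.final_variables == ["B"]


def test_full_selection_protocol_finds_the_driving_variables(cohort):
    """The dual protocol on a synthetic cohort must pick up the strongest
    generating risk factors (age drives the label hardest) and return the
    shipped glycemia cut-point when the trees place one near it."""
    report = run_selection(
        cohort, ["age", "bmi", "waist", "glu", "tg", "hdl", "sex", "psh"],
        folds=5, seed=0, min_leaf=25)
    assert "age" in report.final_variables
    assert "glu" not in report.final_variables          # expert exclusion
    assert report.tree_frequency["glu"] > 4             # but trees split on it
    assert "hdl" in report.final_variables              # shipped override
    assert report.glycemia_cutoff is not None
    assert report.to_dict()["final_variables"] == report.final_variables
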