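import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from survcut import (
    Covariate,
    CovariateSpec,
    RankDeficiencyError,
    StatisticalError,
    SurvivalSample,
    ValidationError,
    default_clinical_spec,
    encode_design,
    fit_cox,
    logrank_test,
    score_test_binary,
    univariate_sweep,
)
from survcut.cox import sweep_report


def log_partial_likelihood(beta, time, event, x):
    """Explicit Breslow log partial likelihood (equals Efron without ties)."""
    ll = 0.0
    for i in np.flatnonzero(event == 1):
        risk = time >= time[i]
        ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
    return ll


def untied_binary_sample(rng, n=40, beta=1.0):
    x = (rng.random(n) < 0.5).astype(float)
    t = rng.exponential(1.0 / (0.05 * np.exp(beta * x)))
    t += rng.uniform(0, 1e-6, n)  # guarantee no ties
    c = rng.uniform(5, 60, n)
    time = np.minimum(t, c)
    event = (t <= c).astype(int)
    return time, event, x


class TestEncodeDesign:
    def cohort_df(self):
        return pd.DataFrame(
            {
                "age": [30.0, 50.0, 60.0],
                "sex": ["female", "male", "female"],
                "risk_group": ["favorable", "intermediate", "adverse"],
                "courses_to_cr": [1, 2, 3],
                "consolidation": ["HDAraC", "AML-87", "AML-201"],
                "dplt_group": ["high", "low", "high"],
            }
        )

    def test_reference_encoding_shapes(self):
        dm = encode_design(self.cohort_df(), default_clinical_spec())
        # age + sex[male] + 2 risk + courses[>1] + 2 consolidation + dplt[low]
        assert dm.X.shape == (3, 8)
        assert "risk_group[intermediate]" in dm.X and "risk_group[adverse]" in dm.X
        assert "risk_group[favorable]" not in dm.X

    def test_courses_collapsed(self):
        dm = encode_design(self.cohort_df(), default_clinical_spec())
        assert dm.X["courses_to_cr[>1]"].tolist() == [0.0, 1.0, 1.0]

    def test_all_reference_row_is_zero(self):
        dm = encode_design(self.cohort_df(), default_clinical_spec())
        row = dm.X.iloc[0].drop("age")
        assert (row == 0).all()  # patient 0 sits at every reference level

    def test_unseen_level_rejected(self):
        df = self.cohort_df()
        df.loc[0, "risk_group"] = "unknown"
        with pytest.raises(ValidationError, match="unknown"):
            encode_design(df, default_clinical_spec())

    def test_listwise_deletion_warns_and_counts(self):
        df = self.cohort_df()
        df.loc[1, "age"] = np.nan
        with pytest.warns(UserWarning, match="dropped listwise"):
            dm = encode_design(df, default_clinical_spec())
        assert dm.n_dropped == 1 and len(dm.X) == 2
        np.testing.assert_array_equal(dm.index, [0, 2])


class TestFitCox:
    def test_null_effect_gives_unit_hazard_ratio(self):
        # identical (time, event) multisets per group: likelihood symmetric
        # under group flip, so the maximum sits at beta = 0
        t = np.tile([3.0, 7.0, 11.0, 15.0, 20.0], 4)
        e = np.tile([1, 1, 0, 1, 0], 4)
        x = np.repeat([0.0, 1.0], 10)
        fit = fit_cox(pd.DataFrame({"g": x}), SurvivalSample(t, e))
        assert abs(fit.coef("g")) < 1e-6
        assert fit.hazard_ratio("g") == pytest.approx(1.0, abs=1e-6)

    def test_matches_brute_force_likelihood_maximum(self, rng):
        time, event, x = untied_binary_sample(rng)
        fit = fit_cox(pd.DataFrame({"x": x}), SurvivalSample(time, event))
        opt = minimize_scalar(
            lambda b: -log_partial_likelihood(b, time, event, x),
            bounds=(-5, 5), method="bounded",
            options={"xatol": 1e-12},
        )
        assert fit.coef("x") == pytest.approx(opt.x, abs=1e-6)
        assert fit.log_likelihood == pytest.approx(-opt.fun, abs=1e-8)

    def test_likelihood_improves_over_null(self, rng):
        time, event, x = untied_binary_sample(rng, beta=0.8)
        fit = fit_cox(pd.DataFrame({"x": x}), SurvivalSample(time, event))
        assert fit.log_likelihood >= log_partial_likelihood(0.0, time, event, x)

    def test_flipping_reference_negates_estimate(self, rng):
        time, event, x = untied_binary_sample(rng)
        s = SurvivalSample(time, event)
        a = fit_cox(pd.DataFrame({"x": x}), s)
        b = fit_cox(pd.DataFrame({"x": 1.0 - x}), s)
        assert a.coef("x") == pytest.approx(-b.coef("x"), abs=1e-8)

    def test_ci_brackets_hazard_ratio(self, rng):
        time, event, x = untied_binary_sample(rng)
        fit = fit_cox(pd.DataFrame({"x": x}), SurvivalSample(time, event))
        row = fit.table.loc["x"]
        assert row["ci_lower"] < row["hr"] < row["ci_upper"]
        assert row["hr"] == pytest.approx(np.exp(row["coef"]))

    def test_rank_deficiency_rejected(self, rng):
        time, event, x = untied_binary_sample(rng)
        X = pd.DataFrame({"x": x, "x2": 2 * x})
        with pytest.raises(RankDeficiencyError):
            fit_cox(X, SurvivalSample(time, event))

    def test_zero_events_rejected(self):
        with pytest.raises(StatisticalError):
            fit_cox(pd.DataFrame({"x": [0.0, 1.0]}), SurvivalSample([1, 2], [0, 0]))

    def test_events_per_coefficient_warning(self, rng):
        time, event, x = untied_binary_sample(rng, n=12)
        with pytest.warns(UserWarning, match="events per coefficient"):
            fit_cox(pd.DataFrame({"x": x}), SurvivalSample(time, event))

    def test_matches_lifelines_with_ties(self, rng):
        # independent implementation check on tied data (both use Efron)
        from lifelines import CoxPHFitter

        n = 120
        x1 = (rng.random(n) < 0.5).astype(float)
        x2 = rng.normal(size=n)
        t = np.ceil(rng.exponential(12 * np.exp(-0.7 * x1 - 0.2 * x2)))  # heavy ties
        c = rng.uniform(5, 40, n)
        time, event = np.minimum(t, c), (t <= c).astype(int)
        fit = fit_cox(pd.DataFrame({"x1": x1, "x2": x2}), SurvivalSample(time, event))
        df = pd.DataFrame({"x1": x1, "x2": x2, "t": time, "e": event})
        cph = CoxPHFitter().fit(df, "t", "e")
        np.testing.assert_allclose(
            fit.table["coef"], cph.summary["coef"], atol=1e-4
        )
        np.testing.assert_allclose(
            fit.table["se"], cph.summary["se(coef)"], atol=1e-4
        )
        assert fit.log_likelihood == pytest.approx(cph.log_likelihood_, abs=1e-5)

    def test_breslow_option(self, rng):
        time, event, x = untied_binary_sample(rng)
        s = SurvivalSample(time, event)
        a = fit_cox(pd.DataFrame({"x": x}), s, ties="efron")
        b = fit_cox(pd.DataFrame({"x": x}), s, ties="breslow")
        assert a.coef("x") == pytest.approx(b.coef("x"), abs=1e-6)  # no ties


class TestScoreTest:
    def test_equals_logrank_on_untied_sample(self, rng):
        for _ in range(5):
            time, event, x = untied_binary_sample(rng)
            chi2, p = score_test_binary(time, event, x)
            lr = logrank_test(
                SurvivalSample(time, event, group=np.where(x > 0, "h", "l"))
            )
            assert chi2 == pytest.approx(lr.chi2, abs=1e-6)
            assert p == pytest.approx(lr.p, abs=1e-6)


class TestSweep:
    def test_report_shape_and_null_coverage(self, effect_cohort):
        df = effect_cohort.to_dataframe()
        cutoff = effect_cohort.metadata["threshold"]
        df["dplt_group"] = np.where(df["dplt"] > cutoff, "high", "low")
        spec = default_clinical_spec()
        sample = effect_cohort.survival_sample("PFS")
        sweep = univariate_sweep(df, spec, sample)
        report = sweep_report(sweep, spec)
        # one row per non-reference level: age, sex, 2 risk, courses, 2 consolidation, dplt
        assert len(report) == 8
        assert set(report["factor"]) == {c.name for c in spec}
        # baseline covariates are independent of outcome by construction:
        # the bulk of their univariate CIs cover 1 (each individually may
        # miss at the nominal 5% rate)
        covering = 0
        for name in ("age", "sex", "risk_group", "courses_to_cr", "consolidation"):
            fit = sweep["univariate"][name]
            for col in fit.table.index:
                row = fit.table.loc[col]
                covering += row["ci_lower"] < 1.0 < row["ci_upper"]
        assert covering >= 5  # of the 7 null coefficients
        # the planted low-marker effect is detected in the joint model
        multi = sweep["multivariate"]
        assert multi.hazard_ratio("dplt_group[low]") > 1.5

    def test_per_covariate_failure_reported_inline(self, effect_cohort):
        df = effect_cohort.to_dataframe()
        df["constant"] = 1.0
        spec = CovariateSpec([Covariate("age", "continuous"),
                              Covariate("constant", "continuous")])
        sweep = univariate_sweep(df, spec, effect_cohort.survival_sample("PFS"))
        assert isinstance(sweep["univariate"]["constant"], Exception)
        assert not isinstance(sweep["univariate"]["age"], Exception)
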