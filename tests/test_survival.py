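import numpy as np
import pytest
from scipy import stats

from survcut import (
    SurvivalSample,
    ValidationError,
    km_estimate,
    logrank_permutation_p,
    logrank_test,
    stratified_logrank,
    survival_rate_at,
)
from conftest import random_sample


def naive_logrank_chi2(time, event, in_a):
    """Independent O/E tabulation over distinct event times (slow loop)."""
    time, event, in_a = map(np.asarray, (time, event, in_a))
    o = e = v = 0.0
    for t in np.unique(time[event == 1]):
        risk = time >= t
        n, n1 = risk.sum(), (risk & in_a).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & in_a).sum()
        o += d1
        e += d * n1 / n
        if n > 1:
            v += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return (o - e) ** 2 / v if v > 0 else 0.0


def two_group_sample(rng, n=20, **kw):
    s = random_sample(rng, n=n, **kw)
    g = rng.random(n) < 0.5
    if g.all() or not g.any():
        g[0] = ~g[0]
    return SurvivalSample(s.time, s.event, group=np.where(g, "a", "b"))


class TestKmEstimate:
    def test_no_censoring_equals_empirical_survival(self):
        curve = km_estimate(SurvivalSample([5, 10, 15], [1, 1, 1]))
        np.testing.assert_allclose(curve.survival, [2 / 3, 1 / 3, 0.0])
        np.testing.assert_array_equal(curve.at_risk, [3, 2, 1])

    def test_all_censored_is_flat_one(self):
        curve = km_estimate(SurvivalSample([5, 10], [0, 0]))
        assert curve.event_times.size == 0
        assert curve.max_time == 10

    def test_hand_tabulated_with_tied_censoring(self):
        # t=2: 4 at risk, 1 event -> 3/4; t=4: censored-at-4 stays at risk,
        # 3 at risk, 1 event -> 1/2; t=6: 1 at risk, 1 event -> 0
        curve = km_estimate(SurvivalSample([2, 4, 4, 6], [1, 1, 0, 1]))
        np.testing.assert_allclose(curve.survival, [0.75, 0.5, 0.0])
        np.testing.assert_array_equal(curve.at_risk, [4, 3, 1])

    def test_matches_one_minus_ecdf_without_censoring(self, rng):
        for _ in range(50):
            t = rng.choice(np.arange(1, 15), size=int(rng.integers(2, 25)))
            curve = km_estimate(SurvivalSample(t, np.ones_like(t)))
            ecdf_surv = [(t > u).mean() for u in curve.event_times]
            np.testing.assert_allclose(curve.survival, ecdf_surv, atol=1e-12)

    def test_matches_lifelines(self, rng):
        from lifelines import KaplanMeierFitter

        s = random_sample(rng, n=60)
        curve = km_estimate(s)
        kmf = KaplanMeierFitter().fit(s.time, s.event)
        ours = [survival_rate_at(curve, t).value for t in curve.event_times]
        theirs = [float(kmf.predict(t)) for t in curve.event_times]
        np.testing.assert_allclose(ours, theirs, atol=1e-10)


class TestSurvivalRateAt:
    def test_is_one_at_zero(self, rng):
        assert survival_rate_at(km_estimate(random_sample(rng)), 0.0).value == 1.0

    def test_step_function_value(self):
        curve = km_estimate(SurvivalSample([5, 10, 15], [1, 1, 1]))
        assert survival_rate_at(curve, 12).value == pytest.approx(1 / 3)
        assert survival_rate_at(curve, 10).value == pytest.approx(1 / 3)

    def test_beyond_followup_flagged(self):
        curve = km_estimate(SurvivalSample([5, 10], [1, 0]))
        res = survival_rate_at(curve, 11)
        assert res.beyond_followup and res.value == pytest.approx(0.5)
        assert not survival_rate_at(curve, 9).beyond_followup

    def test_negative_horizon_rejected(self):
        with pytest.raises(ValidationError):
            survival_rate_at(km_estimate(SurvivalSample([1], [1])), -1)


class TestLogrank:
    def test_identical_groups_give_null(self):
        t = [1, 3, 5, 1, 3, 5]
        e = [1, 0, 1, 1, 0, 1]
        res = logrank_test(SurvivalSample(t, e, group=list("aaabbb")))
        assert res.chi2 == 0.0 and res.p == 1.0

    def test_matches_naive_tabulation(self, rng):
        s = SurvivalSample([1, 2, 3, 4], [1, 1, 1, 1], group=list("aabb"))
        res = logrank_test(s)
        assert res.chi2 == pytest.approx(
            naive_logrank_chi2(s.time, s.event, s.group == "a"), abs=1e-12
        )
        for _ in range(25):
            s = two_group_sample(rng)
            res = logrank_test(s)
            assert res.chi2 == pytest.approx(
                naive_logrank_chi2(s.time, s.event, s.group == "a"), abs=1e-10
            )
            assert res.p == pytest.approx(stats.chi2.sf(res.chi2, 1) if res.chi2 > 0 else 1.0)

    def test_observed_sums_match_expected_sums(self, rng):
        s = two_group_sample(rng, n=30)
        res = logrank_test(s)
        assert sum(res.observed.values()) == pytest.approx(sum(res.expected.values()))
        assert sum(res.observed.values()) == s.event.sum()

    def test_matches_lifelines_on_synthetic_cohort(self, effect_cohort):
        from lifelines.statistics import logrank_test as ll_logrank

        m = effect_cohort.marker("dplt")
        g = m > np.median(m)
        s = effect_cohort.survival_sample("PFS")
        res = logrank_test(SurvivalSample(s.time, s.event, group=np.where(g, "h", "l")))
        ref = ll_logrank(s.time[g], s.time[~g], s.event[g], s.event[~g])
        assert res.chi2 == pytest.approx(ref.test_statistic, abs=1e-8)

    def test_three_groups_match_lifelines(self, rng):
        from lifelines.statistics import multivariate_logrank_test

        s = random_sample(rng, n=45)
        g = rng.integers(0, 3, size=45)
        res = logrank_test(SurvivalSample(s.time, s.event, group=g))
        ref = multivariate_logrank_test(s.time, g, s.event)
        assert res.df == 2
        assert res.chi2 == pytest.approx(ref.test_statistic, abs=1e-8)

    def test_zero_events_warns(self):
        with pytest.warns(UserWarning, match="no events"):
            res = logrank_test(SurvivalSample([1, 2], [0, 0], group=list("ab")))
        assert res.chi2 == 0.0 and res.p == 1.0

    def test_invariant_under_monotone_time_transform(self, rng):
        s = two_group_sample(rng, n=25)
        res = logrank_test(s)
        warped = logrank_test(SurvivalSample(np.exp(s.time / 10), s.event, group=s.group))
        assert warped.chi2 == pytest.approx(res.chi2, abs=1e-12)


class TestPermutationReference:
    def test_exact_versus_monte_carlo(self, rng):
        s = SurvivalSample([1, 2, 5, 6, 8, 9], [1, 1, 1, 1, 1, 1], group=list("aabbab"))
        p_exact = logrank_permutation_p(s)
        p_mc = logrank_permutation_p(s, n_permutations=4000, rng=rng)
        se = np.sqrt(p_exact * (1 - p_exact) / 4000)
        assert abs(p_mc - p_exact) <= 3 * se + 1e-9

    def test_symmetric_sample_has_p_one(self):
        s = SurvivalSample([1, 2, 1, 2], [1, 1, 1, 1], group=list("aabb"))
        assert logrank_permutation_p(s) == 1.0


class TestStratifiedLogrank:
    def test_single_stratum_reduces_to_unstratified(self, rng):
        s = two_group_sample(rng, n=25)
        strat = SurvivalSample(s.time, s.event, group=s.group,
                               stratum=np.zeros(len(s), dtype=int))
        a, b = stratified_logrank(strat), logrank_test(s)
        assert (a.chi2, a.p) == (b.chi2, b.p)  # bit-for-bit
        assert a.observed == b.observed and a.expected == b.expected

    def test_internally_symmetric_strata_give_zero(self):
        t = [1, 2, 1, 2, 5, 7, 5, 7]
        e = [1, 1, 1, 1, 1, 0, 1, 0]
        g = list("aabb") + list("aabb")  # identical (time, event) multisets per group
        strat = [0, 0, 0, 0, 1, 1, 1, 1]
        res = stratified_logrank(SurvivalSample(t, e, group=g, stratum=strat))
        assert res.chi2 == 0.0

    def test_opposite_effects_cancel(self):
        # stratum 0: group a events early; stratum 1: mirror image
        t = [1, 2, 8, 9, 8, 9, 1, 2]
        e = [1] * 8
        g = list("aabb") + list("aabb")
        strat = [0] * 4 + [1] * 4
        per0 = logrank_test(SurvivalSample(t[:4], e[:4], group=g[:4]))
        res = stratified_logrank(SurvivalSample(t, e, group=g, stratum=strat))
        assert per0.chi2 > 2.0  # strong within-stratum effect
        # summed O-E cancels exactly by symmetry
        assert res.observed["a"] == pytest.approx(res.expected["a"], abs=1e-12)
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)

    def test_single_group_stratum_contributes_nothing(self, rng):
        s = two_group_sample(rng, n=20)
        stratum = np.zeros(len(s), dtype=int)
        base = stratified_logrank(SurvivalSample(s.time, s.event, s.group, stratum))
        t2 = np.concatenate([s.time, [3.0, 4.0]])
        e2 = np.concatenate([s.event, [1, 1]])
        g2 = np.concatenate([s.group, ["a", "a"]])
        st2 = np.concatenate([stratum, [1, 1]])
        with pytest.warns(UserWarning, match="single group"):
            res = stratified_logrank(SurvivalSample(t2, e2, g2, st2))
        assert res.chi2 == base.chi2
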