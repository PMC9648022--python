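import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import logrank_test as ll_logrank
from scipy import stats
from sksurv.metrics import cumulative_dynamic_auc
from sksurv.util import Surv

from cervtrans import survival as sv
from cervtrans.ihc import roc_auc
from cervtrans.io import SurvivalCohort
from cervtrans.simulate import SimConfig, gen_survival_cohort


def make_cohort(time, event, **cols):
    df = pd.DataFrame({"patient_id": [f"p{i}" for i in range(len(time))],
                       "time_months": time, "event": event, **cols})
    return SurvivalCohort(data=df)


class TestCensorRule:
    @pytest.mark.parametrize(
        "time,event,exp_time,exp_event",
        [(72, 1, 60, 0), (48, 1, 48, 1), (60, 1, 60, 1)],
    )
    def test_five_year_horizon(self, time, event, exp_time, exp_event):
        c = sv.apply_censor_rule(make_cohort([time], [event]))
        assert c.data.time_months.item() == exp_time
        assert c.data.event.item() == exp_event


class TestKMAndLogrank:
    def test_km_without_censoring_equals_empirical_survival(self, rng):
        t = rng.exponential(10, 40)
        curve = sv.km_estimate(t, np.ones(40, int))
        for i, tt in enumerate(curve.times):
            if tt == 0:
                continue
            emp = (t > tt).mean()
            assert curve.survival[i] == pytest.approx(emp, abs=1e-12)

    def test_identical_groups_give_null_statistic(self, rng):
        t = rng.exponential(10, 30)
        e = (rng.uniform(size=30) < 0.8).astype(int)
        time = np.concatenate([t, t])
        event = np.concatenate([e, e])
        group = np.repeat([0, 1], 30)
        chi2, p = sv.logrank_test(time, event, group)
        assert chi2 == pytest.approx(0.0, abs=1e-12) and p == pytest.approx(1.0)

    def test_matches_lifelines_on_random_data(self, rng):
        for _ in range(10):
            t = rng.exponential(20, 50)
            e = (rng.uniform(size=50) < 0.7).astype(int)
            g = rng.integers(0, 2, 50)
            if e[g == 0].sum() == 0 or e[g == 1].sum() == 0:
                continue
            chi2, p = sv.logrank_test(t, e, g)
            ref = ll_logrank(t[g == 0], t[g == 1], e[g == 0], e[g == 1])
            assert chi2 == pytest.approx(ref.test_statistic, rel=1e-9)
            assert p == pytest.approx(ref.p_value, rel=1e-9)

    def test_power_under_hazard_ratio_three(self):
        rng = np.random.default_rng(31)
        hits = 0
        for _ in range(100):
            t0 = rng.exponential(30, 200)
            t1 = rng.exponential(10, 200)
            time = np.concatenate([t0, t1])
            event = np.ones(400, int)
            group = np.repeat([0, 1], 200)
            _, p = sv.logrank_test(time, event, group)
            hits += p < 0.001
        assert hits >= 99

    def test_null_type_one_error_calibrated(self):
        rng = np.random.default_rng(32)
        rejections = 0
        n_sim = 2000
        for _ in range(n_sim):
            t = rng.exponential(20, 60)
            e = (rng.uniform(size=60) < 0.8).astype(int)
            g = rng.integers(0, 2, 60)
            if e[g == 0].sum() == 0 or e[g == 1].sum() == 0 or len(np.unique(g)) < 2:
                continue
            _, p = sv.logrank_test(t, e, g)
            rejections += p < 0.05
        assert 0.03 <= rejections / n_sim <= 0.07

    def test_empty_group_is_error(self):
        with pytest.raises(ValueError):
            sv.logrank_test([1, 2], [1, 1], [0, 0])


class TestOptimalCutpoint:
    def test_separable_cohort_cuts_at_the_gap(self, rng):
        # low-marker half dies early, high-marker half late; gap at 10
        marker = np.concatenate([rng.uniform(0, 5, 30), rng.uniform(15, 20, 30)])
        time = np.concatenate([rng.uniform(1, 10, 30), rng.uniform(40, 60, 30)])
        res = sv.optimal_cutpoint(time, np.ones(60, int), marker)
        # the selected cutoff is the boundary of the gap between the halves
        assert marker[:30].max() - 1e-9 <= res.cutoff < marker[30:].min()
        assert res.selection_inflated

    def test_null_selection_inflates_naive_p(self):
        rng = np.random.default_rng(33)
        naive_hits = 0
        for _ in range(50):
            t = rng.exponential(20, 60)
            m = rng.normal(size=60)
            res = sv.optimal_cutpoint(t, np.ones(60, int), m)
            naive_hits += res.naive_p < 0.05
        # anti-conservative: nominal 5% level rejected far more often
        assert naive_hits / 50 > 0.15

    def test_permutation_p_restores_calibration_direction(self):
        rng = np.random.default_rng(34)
        t = rng.exponential(20, 50)
        m = rng.normal(size=50)
        res = sv.optimal_cutpoint(t, np.ones(50, int), m, n_permutations=99, seed=1)
        assert res.permutation_p >= res.naive_p

    def test_minprop_half_forces_median_split(self):
        time = np.arange(1.0, 11.0)
        marker = np.arange(10.0)
        res = sv.optimal_cutpoint(time, np.ones(10, int), marker, minprop=0.5)
        assert res.n_low == res.n_high == 5

    def test_no_valid_split_is_error(self):
        with pytest.raises(ValueError):
            sv.optimal_cutpoint([1, 2, 3], [1, 1, 1], [1.0, 1.0, 1.0])


class TestCoxFit:
    def test_two_event_partial_likelihood_closed_form(self):
        # subjects: (t=1, event, x=1), (t=2, event, x=0), (t=3, censored, x=1)
        # dlogL/dbeta = 0  =>  exp(beta) = 1/sqrt(2)
        df = pd.DataFrame({"time_months": [1.0, 2.0, 3.0], "event": [1, 1, 0], "x": [1, 0, 1]})
        res = sv.cox_fit(df, "time_months", "event", ["x"])
        assert res.summary.loc["x", "beta"] == pytest.approx(-0.5 * np.log(2), abs=1e-6)

    def test_null_wald_p_uniform(self):
        rng = np.random.default_rng(35)
        pvals = []
        for _ in range(500):
            n = 120
            t = rng.exponential(20, n)
            c = rng.uniform(0, 60, n)
            x = rng.integers(0, 2, n)
            df = pd.DataFrame(
                {"time_months": np.minimum(t, c), "event": (t <= c).astype(int), "x": x}
            )
            try:
                res = sv.cox_fit(df, "time_months", "event", ["x"])
            except (RuntimeError, ValueError):
                continue
            pvals.append(res.summary.loc["x", "p"])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_score_statistic_matches_logrank_without_ties(self, rng):
        """With a single binary covariate and untied times, the log-rank
        chi-square equals the Cox score test at beta = 0, computed here from
        the partial-likelihood score and information directly."""
        n = 40
        t = np.sort(rng.uniform(1, 100, n))  # distinct times
        e = (rng.uniform(size=n) < 0.7).astype(int)
        x = rng.integers(0, 2, n)
        if e[x == 0].sum() == 0 or e[x == 1].sum() == 0:
            pytest.skip("degenerate draw")
        u = info = 0.0
        for i in range(n):
            if not e[i]:
                continue
            risk = t >= t[i]
            xbar = x[risk].mean()
            u += x[i] - xbar
            info += (x[risk] ** 2).mean() - xbar**2
        chi2, _ = sv.logrank_test(t, e, x)
        assert u**2 / info == pytest.approx(chi2, abs=1e-6)

    def test_constant_covariate_is_error(self):
        df = pd.DataFrame({"time_months": [1, 2, 3], "event": [1, 1, 0], "x": [1, 1, 1]})
        with pytest.raises(ValueError):
            sv.cox_fit(df, "time_months", "event", ["x"])

    def test_separation_is_reported(self):
        df = pd.DataFrame(
            {"time_months": [1, 2, 3, 4, 10, 11, 12, 13],
             "event": [1, 1, 1, 1, 1, 1, 1, 1],
             "x": [1, 1, 1, 1, 0, 0, 0, 0]}
        )
        with pytest.raises(RuntimeError):
            sv.cox_fit(df, "time_months", "event", ["x"])


class TestTimeDependentAUC:
    def test_null_risk_score_near_half(self):
        rng = np.random.default_rng(36)
        t = rng.exponential(40, 1000)
        risk = rng.normal(size=1000)
        res = sv.time_dependent_auc(t, np.ones(1000, int), risk, times=(12, 24, 36))
        assert (np.abs(res.auc - 0.5) < 0.05).all()

    def test_perfect_ranking_gives_auc_one(self):
        t = np.array([5.0, 10.0, 20.0, 40.0, 55.0, 70.0])
        risk = -t  # shorter survival = higher risk, no ties
        res = sv.time_dependent_auc(t, np.ones(6, int), risk, times=(12, 30, 60))
        assert (res.auc == 1.0).all()

    def test_identity_with_empirical_auc_under_no_censoring(self, rng):
        t = rng.exponential(40, 300)
        risk = -t + rng.normal(0, 10, 300)
        for tt in (12, 24, 48):
            a1 = sv.ipcw_auc(t, np.ones(300, int), risk, tt)
            a2 = roc_auc(risk, (t <= tt).astype(int))
            assert a1 == pytest.approx(a2, abs=1e-12)

    def test_matches_scikit_survival_under_censoring(self, rng):
        t = rng.exponential(40, 250)
        e = rng.uniform(size=250) < 0.7
        risk = -t + rng.normal(0, 20, 250)
        y = Surv.from_arrays(e, t)
        times = np.array([12.0, 24.0, 36.0])
        ref, _ = cumulative_dynamic_auc(y, y, risk, times)
        mine = [sv.ipcw_auc(t, e.astype(int), risk, tt) for tt in times]
        np.testing.assert_allclose(mine, ref, atol=1e-10)

    def test_times_beyond_followup_is_error(self, rng):
        t = rng.exponential(5, 50)
        with pytest.raises(ValueError):
            sv.time_dependent_auc(t, np.ones(50, int), -t, times=(10 * t.max(),))

    def test_nested_model_comparison_flags_informative_marker(self):
        rng = np.random.default_rng(37)
        n = 250
        x = rng.normal(size=n)
        t = rng.exponential(30 * np.exp(-1.2 * x))
        res = sv.compare_time_dependent_auc(
            t, np.ones(n, int), risk_full=x, risk_reduced=rng.normal(size=n),
            times=(12, 24), n_boot=200, seed=2,
        )
        assert (res.p_holm < 0.05).any()
        assert (res.p_holm >= res.p - 1e-12).all()


def test_holm_adjustment_hand_example():
    p = np.array([0.01, 0.04, 0.03, 0.005])
    # sorted: .005*4=.02, .01*3=.03, .03*2=.06, .04*1=.06 (monotone max)
    np.testing.assert_allclose(sv.holm_adjust(p), [0.03, 0.06, 0.06, 0.02])


def test_generated_cohort_cox_recovers_protective_marker():
    """At the survival generator defaults (n = 252, marker log-HR = -0.7) the
    Cox fit finds a protective marker with CI excluding 1 in >= 80% of 25
    replicates."""
    rng = np.random.default_rng(38)
    cfg = SimConfig(seed=38)
    hits = 0
    for _ in range(25):
        cohort, _ = gen_survival_cohort(cfg, rng)
        res = sv.cox_fit(
            cohort.data, "time_months", "event", ["marker_group", "age", "figo_stage", "grade"]
        )
        row = res.summary.loc["marker_group"]
        hits += (row.hr < 1) and (row.ci_high < 1)
    assert hits >= 20
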