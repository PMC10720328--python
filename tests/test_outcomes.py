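"""Cluster comparisons, incidence, Kaplan-Meier, Cox and echo risk rules."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import logrank_test

import strainpheno as sp
from strainpheno.outcomes import cox_score, incidence_rates


def _records(times, events, outcome="cv", **extra):
    df = pd.DataFrame(
        {
            f"event_time_{outcome}_years": np.asarray(times, dtype=float),
            f"event_{outcome}": np.asarray(events, dtype=int),
        }
    )
    for k, v in extra.items():
        df[k] = v
    return df


class TestCompareClusters:
    def test_identical_data_gives_p_one(self):
        vals = np.arange(50, dtype=float)
        rec = pd.DataFrame({"age": np.concatenate([vals, vals]),
                            "smoking": np.tile([0, 1], 50)})
        labels = np.repeat([1, 2], 50)
        cmp_ = sp.compare_clusters(rec, labels, continuous=["age"],
                                   categorical=["smoking"])
        assert (cmp_.pairwise.p == 1.0).all()
        assert (cmp_.pairwise.statistic == 0.0).all()

    def test_type_one_error_near_nominal(self):
        rng = np.random.default_rng(0)
        labels = np.repeat([1, 2], 200)
        hits = 0
        n_sim = 200
        for _ in range(n_sim):
            rec = pd.DataFrame({"x": rng.normal(size=400)})
            cmp_ = sp.compare_clusters(rec, labels, continuous=["x"],
                                       categorical=[])
            hits += int(cmp_.pairwise.p.iloc[0] < 0.05)
        assert 0.01 < hits / n_sim < 0.11  # ~5% false positives

    def test_two_sd_shift_detected(self):
        rng = np.random.default_rng(1)
        rec = pd.DataFrame({"x": np.concatenate([rng.normal(0, 1, 100),
                                                 rng.normal(2, 1, 100)])})
        cmp_ = sp.compare_clusters(rec, np.repeat([1, 2], 100),
                                   continuous=["x"], categorical=[])
        assert cmp_.pairwise.p.iloc[0] < 1e-6
        assert cmp_.pairwise.significant.iloc[0]

    def test_needs_two_clusters(self):
        rec = pd.DataFrame({"x": np.arange(10.0)})
        with pytest.raises(ValueError):
            sp.compare_clusters(rec, np.ones(10), continuous=["x"])


class TestIncidenceRates:
    def test_cohort_worked_example(self):
        """116 first events over 10,291 person-years -> 11.3 per 1,000 py."""
        n = 1000
        events = np.zeros(n, dtype=int)
        events[:116] = 1
        times = np.full(n, 5.0)
        times[116:] = (10291.0 - 116 * 5.0) / (n - 116)
        rates = incidence_rates(_records(times, events), None)
        overall = rates[rates.cluster == "overall"].iloc[0]
        assert overall.events == 116
        assert overall.person_years == pytest.approx(10291.0)
        assert round(overall.rate_per_1000py, 1) == 11.3

    def test_zero_events_zero_rate(self):
        rates = incidence_rates(_records([2.0, 3.0], [0, 0]), None)
        assert (rates.rate_per_1000py == 0).all()

    def test_doubling_follow_up_halves_rate(self):
        t = [1.0, 2.0, 3.0, 4.0]
        e = [1, 0, 1, 0]
        r1 = incidence_rates(_records(t, e), None)
        r2 = incidence_rates(_records([2 * x for x in t], e), None)
        assert r2.rate_per_1000py.iloc[-1] == pytest.approx(
            r1.rate_per_1000py.iloc[-1] / 2
        )

    def test_cluster_totals_sum_to_cohort(self, outcome_table, fitted):
        _, _, labels = fitted
        rates = sp.incidence_rates(outcome_table, labels, outcome="cv")
        per = rates[rates.cluster != "overall"]
        tot = rates[rates.cluster == "overall"].iloc[0]
        assert per.events.sum() == tot.events
        assert per.person_years.sum() == pytest.approx(tot.person_years)

    def test_nonpositive_time_rejected(self):
        with pytest.raises(ValueError):
            incidence_rates(_records([0.0, 1.0], [0, 1]), None)


class TestKaplanMeier:
    def test_six_subject_hand_example(self):
        # times 1, 2+, 3, 4, 4+, 5 ('+' censored); product-limit by hand:
        # S(1)=5/6, S(3)=5/6*3/4, S(4)=...*2/3, S(5)=0
        rec = _records([1, 2, 3, 4, 4, 5], [1, 0, 1, 1, 0, 1])
        km = sp.km_cumulative_incidence(rec, None)[0]
        s = km.set_index("time")["survival"]
        assert s[1.0] == pytest.approx(5 / 6)
        assert s[3.0] == pytest.approx(5 / 6 * 3 / 4)
        assert s[4.0] == pytest.approx(5 / 6 * 3 / 4 * 2 / 3)
        assert s[5.0] == pytest.approx(0.0)
        np.testing.assert_allclose(
            km.cumulative_incidence, 1 - km.survival, atol=1e-12
        )

    def test_no_censoring_matches_empirical_survival(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(5, 100)
        km = sp.km_cumulative_incidence(_records(t, np.ones(100)), None)[0]
        for _, row in km.iloc[1:].iterrows():
            emp = np.mean(t > row.time)
            assert row.survival == pytest.approx(emp, abs=1e-10)

    def test_all_censored_survival_one(self):
        km = sp.km_cumulative_incidence(_records([1, 2, 3], [0, 0, 0]), None)[0]
        np.testing.assert_allclose(km.survival, 1.0)

    def test_matches_brute_force_product_limit(self):
        rng = np.random.default_rng(3)
        t = np.round(rng.exponential(4, 60), 1) + 0.1  # force ties
        e = rng.integers(0, 2, 60)
        km = sp.km_cumulative_incidence(_records(t, e), None)[0]
        # oracle: explicit product over risk sets
        for _, row in km.iterrows():
            s = 1.0
            for u in np.unique(t[(e == 1) & (t <= row.time)]):
                n_risk = np.sum(t >= u)
                d = np.sum((t == u) & (e == 1))
                s *= 1 - d / n_risk
            assert row.survival == pytest.approx(s, abs=1e-12)

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError):
            sp.km_cumulative_incidence(_records([-1, 2], [1, 1]), None)


class TestCox:
    def _two_group(self, hr=2.0, n=2000, seed=0):
        rng = np.random.default_rng(seed)
        labels = np.repeat([1, 2], n // 2)
        h = np.where(labels == 1, 0.05, 0.05 * hr)
        t = rng.exponential(1 / h)
        c = rng.uniform(5, 25, n)
        rec = _records(np.minimum(t, c), (t <= c).astype(int))
        return rec, labels

    def test_null_gives_unit_hazard_ratios(self):
        rec, labels = self._two_group(hr=1.0, seed=1)
        res = sp.cox_cluster_hr(rec, labels, covariates=[], outcome="cv")
        assert res.cluster_effects.beta.sum() == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(res.cluster_effects.hr, 1.0, atol=0.15)

    def test_score_vanishes_at_estimate(self):
        rec, labels = self._two_group(seed=2)
        res = sp.cox_cluster_hr(rec, labels, covariates=[], outcome="cv")
        X = np.where(labels == 1, 1.0, -1.0)[:, None]
        score = cox_score(
            np.array([res.cluster_effects.beta.iloc[0]]),
            X,
            rec["event_time_cv_years"].to_numpy(),
            rec["event_cv"].to_numpy(),
        )
        assert np.abs(score).max() < 1e-6

    def test_deviation_coding_recovers_sqrt_hr(self):
        rec, labels = self._two_group(hr=2.0, seed=3)
        res = sp.cox_cluster_hr(rec, labels, covariates=[], outcome="cv")
        hrs = res.cluster_effects.set_index("cluster").hr
        assert hrs[1] == pytest.approx(1 / np.sqrt(2), rel=0.1)
        assert hrs[2] == pytest.approx(np.sqrt(2), rel=0.1)

    def test_score_test_equals_logrank(self):
        """Breslow score test at beta=0 for one binary covariate = log-rank."""
        rng = np.random.default_rng(4)
        n = 300
        g = rng.integers(0, 2, n)
        t = rng.exponential(np.where(g == 1, 5.0, 8.0))
        e = np.ones(n, dtype=int)
        X = g.astype(float)[:, None]
        u = cox_score(np.zeros(1), X, t, e)[0]
        eps = 1e-5
        info = -(cox_score(np.array([eps]), X, t, e)[0]
                 - cox_score(np.array([-eps]), X, t, e)[0]) / (2 * eps)
        chi2_score = u**2 / info
        ref = logrank_test(t[g == 0], t[g == 1], np.ones((g == 0).sum()),
                           np.ones((g == 1).sum()))
        assert chi2_score == pytest.approx(ref.test_statistic, rel=1e-4)

    def test_adjusted_fit_on_synthetic_cohort(self, outcome_table, fitted):
        _, _, labels = fitted
        with pytest.warns(UserWarning, match="events"):
            res = sp.cox_cluster_hr(outcome_table, labels, outcome="cv")
        assert res.cluster_effects.beta.sum() == pytest.approx(0.0, abs=1e-10)
        assert len(res.covariate_effects) == 8
        # risk gradient: canonical cluster 1 below cohort average, last above
        hrs = res.cluster_effects.set_index("cluster").hr
        assert hrs[1] < 1.0 < hrs[4]


class TestRiskRules:
    def _rec(self, **kw):
        base = dict(e_over_eprime=np.nan, la_peak_strain=np.nan, lavi=np.nan,
                    tr_velocity=np.nan, mitral_a_duration_ms=np.nan,
                    pv_reversal_duration_ms=np.nan, lvmi_gm27=np.nan,
                    female=np.nan)
        base.update(kw)
        return pd.DataFrame([base])

    def test_definite_dysfunction_by_e_over_eprime(self):
        out = sp.classify_risk_rules(self._rec(e_over_eprime=10.0))
        assert out.diastolic_dysfunction.iloc[0] == True  # noqa: E712

    def test_borderline_with_low_la_strain(self):
        out = sp.classify_risk_rules(
            self._rec(e_over_eprime=9.0, la_peak_strain=20.0)
        )
        assert out.diastolic_dysfunction.iloc[0] == True  # noqa: E712

    def test_borderline_all_ancillary_normal(self):
        out = sp.classify_risk_rules(
            self._rec(e_over_eprime=9.0, la_peak_strain=30.0, lavi=30.0,
                      tr_velocity=2.0, mitral_a_duration_ms=140.0,
                      pv_reversal_duration_ms=100.0)
        )
        assert out.diastolic_dysfunction.iloc[0] == False  # noqa: E712

    def test_prolonged_reverse_atrial_flow_branch(self):
        out = sp.classify_risk_rules(
            self._rec(e_over_eprime=9.0, la_peak_strain=30.0, lavi=30.0,
                      tr_velocity=2.0, mitral_a_duration_ms=120.0,
                      pv_reversal_duration_ms=135.0)
        )
        assert out.diastolic_dysfunction.iloc[0] == True  # noqa: E712

    def test_missing_inputs_propagate_unknown(self):
        out = sp.classify_risk_rules(self._rec())
        assert out.diastolic_dysfunction.isna().iloc[0]
        assert out.lv_hypertrophy.isna().iloc[0]
        # borderline with some missing ancillary but one positive -> True
        out = sp.classify_risk_rules(self._rec(e_over_eprime=9.0, lavi=50.0))
        assert out.diastolic_dysfunction.iloc[0] == True  # noqa: E712
        # borderline, available ancillary normal, others missing -> unknown
        out = sp.classify_risk_rules(self._rec(e_over_eprime=9.0, lavi=30.0))
        assert out.diastolic_dysfunction.isna().iloc[0]

    def test_lvh_sex_specific_thresholds(self):
        rec = pd.DataFrame(
            {
                "lvmi_gm27": [51.0, 48.0, 48.0, 46.0],
                "female": [0, 0, 1, 1],
            }
        )
        out = sp.classify_risk_rules(rec)
        assert list(out.lv_hypertrophy) == [True, False, True, False]
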