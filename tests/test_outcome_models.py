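"""Person-month expansion, pooled logistic hazards, risk curves, contrasts,
hazard ratios (discrete and Cox), effect modification."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from equipoise import (ARMS, approximate_hr, contrast, expand_person_months,
                       fit_cox, fit_hazard_from_followup,
                       fit_pooled_logistic, followup_arrays,
                       predict_risk_curve, wald_interaction_test)
from equipoise.outcome_models import HazardModel


def make_model(intercept, slope=0.0, arm_effects=None, interaction=False):
    arm_effects = arm_effects or {}
    cols = ["_intercept", "t"] + [f"arm={a}" for a in ARMS[1:]]
    coef = [intercept, slope] + [arm_effects.get(a, 0.0) for a in ARMS[1:]]
    if interaction:
        cols += [f"arm={a}:t" for a in ARMS[1:]]
        coef += [0.0] * 3
    return HazardModel(arms=ARMS, columns=cols, coef=np.asarray(coef, float),
                       include_time_interaction=interaction)


class TestExpansion:
    def _cohort(self, rows):
        df = pd.DataFrame(rows)
        df["patient_id"] = np.arange(1, len(df) + 1)
        df["arm"] = df.get("arm", "olanzapine")
        df["itt_event_month"] = pd.array(df["ev"], dtype="Int64")
        df["itt_censor_month"] = pd.array(df["cn"], dtype="Int64")
        return df

    def test_censored_patient_contributes_event_free_rows(self):
        pm = expand_person_months(self._cohort(
            [{"ev": None, "cn": 3}]))
        assert len(pm) == 3
        assert pm["event"].sum() == 0
        assert list(pm["t"]) == [1, 2, 3]

    def test_event_in_month_one_gives_single_event_row(self):
        pm = expand_person_months(self._cohort([{"ev": 1, "cn": None}]))
        assert len(pm) == 1 and pm.loc[0, "event"] == 1

    def test_mixed_toy_row_count_is_sum_of_terminal_months(self):
        rows = [{"ev": 5, "cn": None}, {"ev": None, "cn": 12},
                {"ev": 60, "cn": None}, {"ev": None, "cn": 60},
                {"ev": None, "cn": 1}]
        pm = expand_person_months(self._cohort(rows))
        assert len(pm) == 5 + 12 + 60 + 60 + 1
        assert pm["event"].sum() == 2
        # at most one event row per patient, and it is the last
        last = pm.groupby("patient_id").tail(1)
        assert last.set_index("patient_id")["event"].sum() == 2
        assert pm[pm["event"] == 1]["t"].tolist() == [5, 60]

    def test_consecutive_months_per_patient(self, cohort):
        pm = expand_person_months(cohort.head(200))
        for _, g in pm.groupby("patient_id"):
            assert list(g["t"]) == list(range(1, len(g) + 1))


class TestPooledLogistic:
    def test_recovers_constant_hazard_within_3_se(self):
        rng = np.random.default_rng(21)
        n, h = 20000, 0.02
        T = np.minimum(rng.geometric(h, n), 60)
        event = T < 60
        event |= (T == 60) & (rng.random(n) < h)   # event exactly at 60
        pm = pd.DataFrame({"patient_id": np.arange(n), "t": T,
                           "arm": "olanzapine", "event": event.astype(int)})
        pm = expandish(pm)
        fit = fit_pooled_logistic(pm, include_time_interaction=False,
                                  arms=("olanzapine",))
        se = np.sqrt(np.diag(fit.fit.cov))
        coefs = dict(zip(fit.columns, fit.coef))
        assert abs(coefs["_intercept"] - logit(h)) < 3 * se[0]
        assert abs(coefs["t"]) < 3 * se[1]

    def test_weight_scale_invariance(self, cohort):
        T, ev = followup_arrays(cohort)
        arm = cohort["arm"].to_numpy()
        w = np.random.default_rng(3).uniform(0.5, 2.0, len(cohort))
        m1 = fit_hazard_from_followup(T, ev, arm, w, ARMS)
        m2 = fit_hazard_from_followup(T, ev, arm, 2.0 * w, ARMS)
        assert np.allclose(m1.coef, m2.coef, atol=1e-9)

    def test_identical_arm_patterns_give_zero_arm_effects(self):
        T = np.tile([10, 20, 60, 60], 4)
        ev = np.tile([True, True, False, False], 4)
        arm = np.repeat(list(ARMS), 4)
        m = fit_hazard_from_followup(T, ev, arm, None, ARMS)
        for name, b in zip(m.columns, m.coef):
            if name.startswith("arm="):
                assert abs(b) < 1e-7, name

    def test_grouped_fast_path_matches_person_month_fit(self, cohort):
        """The collapsed (arm, month) binomial fit must equal the row-level
        person-month fit exactly."""
        T, ev = followup_arrays(cohort)
        w = np.random.default_rng(4).uniform(0.2, 3.0, len(cohort))
        fast = fit_hazard_from_followup(T, ev, cohort["arm"].to_numpy(), w,
                                        ARMS)
        pm = expand_person_months(cohort, weights=w)
        slow = fit_pooled_logistic(pm, arms=ARMS)
        assert np.allclose(fast.coef, slow.coef, atol=1e-8)

    def test_matches_statsmodels_glm(self, cohort):
        sm = pytest.importorskip("statsmodels.api")
        w = np.random.default_rng(5).uniform(0.2, 3.0, len(cohort))
        pm = expand_person_months(cohort, weights=w)
        fit = fit_pooled_logistic(pm, arms=ARMS)
        from equipoise.outcome_models import _hazard_design
        X, _ = _hazard_design(pm["t"].to_numpy(), pm["arm"].to_numpy(),
                              ARMS, "linear", (), True)
        ref = sm.GLM(pm["event"].to_numpy(), X,
                     family=sm.families.Binomial(),
                     var_weights=pm["weight"].to_numpy()).fit()
        assert np.allclose(fit.coef, ref.params, atol=1e-6)

    def test_no_events_rejected(self):
        pm = pd.DataFrame({"patient_id": [1], "t": [1],
                           "arm": ["olanzapine"], "event": [0]})
        with pytest.raises(ValueError, match="no events"):
            fit_pooled_logistic(pm, arms=("olanzapine",))


def expandish(per_patient):
    """Expand a minimal per-patient frame to person-months."""
    T = per_patient["t"].to_numpy()
    idx = np.repeat(np.arange(len(per_patient)), T)
    month = np.arange(T.sum()) - np.repeat(np.cumsum(T) - T, T) + 1
    last = month == np.repeat(T, T)
    return pd.DataFrame({
        "patient_id": per_patient["patient_id"].to_numpy()[idx],
        "t": month, "arm": per_patient["arm"].to_numpy()[idx],
        "event": (last & np.repeat(
            per_patient["event"].to_numpy(bool), T)).astype(int)})


class TestRiskCurves:
    def test_constant_hazard_closed_form(self):
        m = make_model(logit(0.01))
        R = predict_risk_curve(m, "olanzapine", 60)
        assert R[60] == pytest.approx(1 - 0.99 ** 60, abs=1e-12)
        assert R[0] == 0.0

    def test_zero_hazard_gives_zero_risk(self):
        m = make_model(-500.0)
        assert predict_risk_curve(m, "aripiprazole", 60).max() == \
            pytest.approx(0.0, abs=1e-100)

    def test_matches_brute_force_product_oracle(self):
        rng = np.random.default_rng(22)
        for _ in range(100):
            m = make_model(rng.normal(-6, 1), rng.normal(0, 0.02),
                           {a: rng.normal(0, 0.3) for a in ARMS[1:]},
                           interaction=False)
            arm = ARMS[rng.integers(0, 4)]
            R = predict_risk_curve(m, arm, 60)
            h = m.predict_hazard(arm, np.arange(1, 61))
            brute = 0.0
            surv = 1.0
            for t in range(60):
                surv *= (1 - h[t])
            assert R[60] == pytest.approx(1 - surv, abs=1e-12)

    def test_monotone_and_bounded(self, cohort):
        T, ev = followup_arrays(cohort)
        m = fit_hazard_from_followup(T, ev, cohort["arm"].to_numpy(), None,
                                     ARMS, time_spec="spline")
        for a in ARMS:
            R = predict_risk_curve(m, a, 60)
            assert (np.diff(R) >= 0).all() and R[-1] <= 1

    def test_horizon_beyond_followup_rejected(self):
        with pytest.raises(ValueError):
            predict_risk_curve(make_model(-5.0), "olanzapine", 61)


class TestContrast:
    def test_arithmetic(self):
        Ra = np.zeros(61)
        Rc = np.zeros(61)
        Ra[60], Rc[60] = 0.050, 0.057
        c = contrast(Ra, Rc, 60)
        assert c["rd_per_1000"] == pytest.approx(-7.0)
        assert c["rr"] == pytest.approx(0.050 / 0.057)

    def test_identical_curves_are_null(self):
        R = np.linspace(0, 0.1, 61)
        c = contrast(R, R, 60)
        assert c["rd_per_1000"] == 0.0 and c["rr"] == 1.0

    def test_six_month_horizon_reads_same_curve(self):
        m = make_model(logit(0.01))
        R = predict_risk_curve(m, "olanzapine", 60)
        c = contrast(R, R, 6)
        assert c["risk_index"] == pytest.approx(1 - 0.99 ** 6, abs=1e-12)

    def test_zero_comparator_risk_flags_rr(self):
        Ra, Rc = np.full(61, 0.1), np.zeros(61)
        assert np.isnan(contrast(Ra, Rc, 60)["rr"])


class TestHazardRatios:
    def _simulate(self, hr, n=20000, h0=0.004, seed=23):
        """Two-arm rare-event survival with a known hazard ratio."""
        rng = np.random.default_rng(seed)
        arm = np.asarray(["aripiprazole", "risperidone"],
                         object)[rng.integers(0, 2, n)]
        h = np.where(arm == "aripiprazole", h0 * hr, h0)
        draw = rng.geometric(h)           # month of event
        T = np.minimum(draw, 60)
        event = draw <= 60
        return pd.DataFrame({
            "patient_id": np.arange(n), "arm": arm,
            "itt_event_month": pd.array(np.where(event, T, np.nan),
                                        dtype="Int64"),
            "itt_censor_month": pd.array(np.where(event, np.nan, 60),
                                         dtype="Int64")})

    def test_null_simulation_hr_near_one(self):
        df = self._simulate(1.0)
        T, ev = followup_arrays(df)
        arms = ("aripiprazole", "risperidone")
        m = fit_hazard_from_followup(T, ev, df["arm"].to_numpy(), None, arms,
                                     include_time_interaction=False)
        hr = approximate_hr(m)["risperidone"]
        se = np.sqrt(np.diag(m.fit.cov))[m.columns.index("arm=risperidone")]
        assert abs(np.log(hr)) < 3 * se

    def test_rare_event_recovery_of_true_hr(self):
        df = self._simulate(0.6)
        T, ev = followup_arrays(df)
        arms = ("aripiprazole", "risperidone")
        m = fit_hazard_from_followup(T, ev, df["arm"].to_numpy(), None, arms,
                                     include_time_interaction=False)
        hr = approximate_hr(m)["risperidone"]   # arip vs risp
        se = np.sqrt(np.diag(m.fit.cov))[m.columns.index("arm=risperidone")]
        assert abs(np.log(hr) - np.log(0.6)) < 3 * se

    def test_interaction_model_rejected_for_hr(self):
        with pytest.raises(ValueError):
            approximate_hr(make_model(-5.0, interaction=True))

    def test_cox_recovers_true_hr_and_matches_plr(self):
        df = self._simulate(0.6, n=10000)
        T, ev = followup_arrays(df)
        arms = ("aripiprazole", "risperidone")
        cox = fit_cox(df, arms=arms)
        hr_cox = cox.hr["risperidone"]
        se = np.sqrt(cox.cov.loc["arm=risperidone", "arm=risperidone"])
        assert abs(np.log(hr_cox) - np.log(0.6)) < 3 * se
        m = fit_hazard_from_followup(T, ev, df["arm"].to_numpy(), None, arms,
                                     include_time_interaction=False)
        hr_plr = approximate_hr(m)["risperidone"]
        assert abs(hr_cox - hr_plr) / hr_plr < 0.05

    def test_cox_weight_doubling_invariance(self, cohort):
        w = np.random.default_rng(7).uniform(0.5, 2.0, len(cohort))
        a = fit_cox(cohort, w, arms=ARMS).hr
        b = fit_cox(cohort, 2 * w, arms=ARMS).hr
        for k in a:
            assert a[k] == pytest.approx(b[k], rel=1e-6)


class TestEffectModification:
    def test_zero_interaction_coefficients_give_p_one(self):
        from scipy import stats
        b = np.zeros(3)
        V = np.eye(3)
        stat = b @ np.linalg.solve(V, b)
        assert stats.chi2.sf(stat, 3) == 1.0

    def test_strong_age_interaction_detected(self, complete_cohort):
        """Arm x age interaction injected into follow-up: the Wald test
        must reject."""
        _, _, cohort = complete_cohort
        df = cohort.copy()
        rng = np.random.default_rng(8)
        # regenerate outcomes with an aripiprazole x age hazard interaction
        age_std = (df["age"] - df["age"].mean()) / df["age"].std()
        eta = logit(0.004) + np.where(df["arm"] == "aripiprazole",
                                      1.2 * age_std, 0.0)
        h = expit(eta)
        draw = rng.geometric(np.clip(h, 1e-6, 1))
        T = np.minimum(draw, 60)
        event = draw <= 60
        df["itt_event_month"] = pd.array(np.where(event, T, np.nan),
                                         dtype="Int64")
        df["itt_censor_month"] = pd.array(np.where(event, np.nan, 60),
                                          dtype="Int64")
        p = wald_interaction_test(df, np.ones(len(df)), "age")
        assert p < 0.01

    def test_null_interaction_not_systematically_rejected(self,
                                                          complete_cohort):
        _, _, cohort = complete_cohort
        p = wald_interaction_test(cohort, np.ones(len(cohort)), "sex")
        assert p > 0.001   # sanity: no spurious tiny p under the null

    def test_constant_modifier_rejected(self, complete_cohort):
        _, _, cohort = complete_cohort
        df = cohort.copy()
        df["sex"] = "F"
        with pytest.raises(ValueError, match="constant"):
            wald_interaction_test(df, np.ones(len(df)), "sex")
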