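"""Cohort construction: eligibility boundaries, outcome coding rules,
per-protocol censoring, dose conversion, and a day-level brute-force oracle."""

import numpy as np
import pandas as pd
import pytest

from equipoise import (ARMS, EligibilityCriteria, apply_eligibility,
                       build_cohort, derive_outcomes, derive_per_protocol,
                       olanzapine_equivalent_dose)
from equipoise.config import MONTH_DAYS
from equipoise.simulate import RawTables

from conftest import (empty_adverse, empty_deaths, empty_episodes, toy_rx,
                      toy_patients)


def _tables(patients, rx, episodes=None, deaths=None, adverse=None):
    return RawTables(
        patients=patients, prescriptions=rx,
        episodes=episodes if episodes is not None else empty_episodes(),
        deaths=deaths if deaths is not None else empty_deaths(),
        adverse_reactions=adverse if adverse is not None else empty_adverse())


IDX = "2010-06-15"


class TestEligibility:
    @pytest.mark.parametrize("birth_year,included", [
        (1971, False),   # aged 39 at index
        (1970, True),    # aged 40: boundary inclusion
        (1911, True),    # aged 99
        (1910, False),   # aged 100
    ])
    def test_age_boundaries(self, birth_year, included):
        pats = toy_patients(1, birth_year=[birth_year])
        rx = toy_rx([(1, IDX, "olanzapine", 10.0, False, False)])
        cohort, tally = apply_eligibility(_tables(pats, rx))
        assert (len(cohort) == 1) == included
        assert tally["age"] == (0 if included else 1)

    @pytest.mark.parametrize("lag_days,included", [(25, True), (30, True),
                                                   (31, False)])
    def test_smi_diagnosis_grace_window_after_index(self, lag_days, included):
        """An SMI code up to 30 days after index keeps the patient in."""
        pats = toy_patients(
            1, smi_diagnosis_date=[pd.Timestamp(IDX)
                                   + pd.Timedelta(days=lag_days)])
        rx = toy_rx([(1, IDX, "quetiapine", 200.0, False, False)])
        cohort, tally = apply_eligibility(_tables(pats, rx))
        assert (len(cohort) == 1) == included

    def test_inclusive_smi_variant_admits_late_diagnoses(self):
        pats = toy_patients(
            1, smi_diagnosis_date=[pd.Timestamp(IDX) + pd.Timedelta(days=200)])
        rx = toy_rx([(1, IDX, "quetiapine", 200.0, False, False)])
        assert len(apply_eligibility(_tables(pats, rx))[0]) == 0
        crit = EligibilityCriteria(inclusive_smi=True)
        assert len(apply_eligibility(_tables(pats, rx), crit)[0]) == 1

    def test_six_patient_fixture_one_violation_each(self):
        """One violation per criterion: nobody included, tally = 1 each."""
        idx = pd.Timestamp(IDX)
        pats = toy_patients(6)
        pats.loc[0, "birth_year"] = 1975                      # age 35
        pats.loc[1, "registration_date"] = idx - pd.Timedelta(days=100)
        pats.loc[2, "practice_linkage_eligible"] = False
        pats.loc[3, "smi_diagnosis_date"] = idx + pd.Timedelta(days=60)
        rx = toy_rx(
            [(i, IDX, "risperidone", 4.0, False, False) for i in range(1, 7)]
            + [(5, "2010-05-01", "olanzapine", 10.0, False, True)]   # LAI -45d
        )
        rx.loc[rx["patient_id"] == 6, "pro_re_nata"] = True
        cohort, tally = apply_eligibility(_tables(pats, rx))
        assert len(cohort) == 0
        for crit in ("age", "registration_under_6m", "not_linkage_eligible",
                     "no_smi_at_index", "lai_prior_90d", "pro_re_nata_first"):
            assert tally[crit] == 1, crit

    def test_co_prescription_at_index_excluded(self):
        pats = toy_patients(1)
        rx = toy_rx([(1, IDX, "olanzapine", 10.0, False, False),
                     (1, IDX, "risperidone", 4.0, False, False)])
        cohort, tally = apply_eligibility(_tables(pats, rx))
        assert len(cohort) == 0 and tally["co_prescription_at_index"] == 1

    def test_prior_mace_episode_excluded(self):
        pats = toy_patients(1)
        rx = toy_rx([(1, IDX, "olanzapine", 10.0, False, False)])
        ep = pd.DataFrame([{"patient_id": 1,
                            "admission_date": pd.Timestamp("2009-01-01"),
                            "primary_icd10": "I219"}])
        cohort, tally = apply_eligibility(_tables(pats, rx, episodes=ep))
        assert len(cohort) == 0 and tally["prior_history"] == 1

    def test_empty_prescriptions_warns_not_fails(self):
        pats = toy_patients(2)
        with pytest.warns(UserWarning, match="empty"):
            cohort, tally = apply_eligibility(_tables(pats, toy_rx([])))
        assert cohort.empty

    def test_flow_conservation_and_idempotence(self, raw_tables):
        cohort, tally = apply_eligibility(raw_tables)
        n_candidates = raw_tables.prescriptions["patient_id"].nunique()
        assert sum(tally.values()) + len(cohort) == n_candidates
        # re-applying eligibility to the already-included patients removes no one
        kept = raw_tables.patients[
            raw_tables.patients["patient_id"].isin(cohort["patient_id"])]
        rx = raw_tables.prescriptions[
            raw_tables.prescriptions["patient_id"].isin(cohort["patient_id"])]
        sub = RawTables(patients=kept.reset_index(drop=True), prescriptions=rx,
                        episodes=raw_tables.episodes, deaths=raw_tables.deaths,
                        adverse_reactions=raw_tables.adverse_reactions)
        cohort2, tally2 = apply_eligibility(sub)
        assert len(cohort2) == len(cohort)
        assert sum(tally2.values()) == 0


class TestOutcomes:
    def _skeleton(self, n=1):
        pats = toy_patients(n)
        rx = toy_rx([(i, IDX, "olanzapine", 10.0, False, False)
                     for i in range(1, n + 1)])
        cohort, _ = apply_eligibility(_tables(pats, rx))
        return cohort

    def test_mi_episode_is_event_at_its_month(self):
        cohort = self._skeleton()
        ep = pd.DataFrame([{"patient_id": 1,
                            "admission_date": pd.Timestamp(IDX)
                            + pd.Timedelta(days=200),   # month 7
                            "primary_icd10": "I219"}])
        out = derive_outcomes(cohort, ep, empty_deaths())
        assert out.loc[0, "itt_event_month"] == 7
        assert out.loc[0, "itt_event_type"] == "mi"
        assert pd.isna(out.loc[0, "itt_censor_month"])

    def test_death_within_28_days_of_stroke_codes_cv_death(self):
        cohort = self._skeleton()
        ep = pd.DataFrame([{"patient_id": 1,
                            "admission_date": pd.Timestamp(IDX)
                            + pd.Timedelta(days=100),
                            "primary_icd10": "I639"}])
        de = pd.DataFrame([{"patient_id": 1,
                            "date": pd.Timestamp(IDX) + pd.Timedelta(days=120),
                            "underlying_cause_icd10": "C509"}])   # any cause
        out = derive_outcomes(cohort, ep, de)
        assert out.loc[0, "itt_event_type"] == "cv_death"
        assert out.loc[0, "itt_event_month"] == 4   # stroke month (day 100)

    def test_noncv_death_censors_at_its_month(self):
        cohort = self._skeleton()
        de = pd.DataFrame([{"patient_id": 1,
                            "date": pd.Timestamp(IDX) + pd.Timedelta(days=900),
                            "underlying_cause_icd10": "C349"}])
        out = derive_outcomes(cohort, empty_episodes(), de)
        assert pd.isna(out.loc[0, "itt_event_month"])
        assert out.loc[0, "itt_censor_month"] == 30
        assert out.loc[0, "itt_censor_reason"] == "noncv_death"

    def test_no_events_censors_at_horizon(self):
        out = derive_outcomes(self._skeleton(), empty_episodes(),
                              empty_deaths())
        assert out.loc[0, "itt_censor_month"] == 60
        assert out.loc[0, "itt_censor_reason"] == "horizon"

    def test_event_before_index_rejected(self):
        cohort = self._skeleton()
        ep = pd.DataFrame([{"patient_id": 1,
                            "admission_date": pd.Timestamp("2010-06-10"),
                            "primary_icd10": "I21"}])
        cohort2 = cohort.copy()   # bypass eligibility's history screen
        with pytest.raises(ValueError, match="before index"):
            derive_outcomes(cohort2, ep, empty_deaths())


class TestPerProtocol:
    def _with_outcomes(self, rx_entries, adverse=None, n=1):
        pats = toy_patients(n)
        rx = toy_rx(rx_entries)
        cohort, _ = apply_eligibility(_tables(pats, rx))
        cohort = derive_outcomes(cohort, empty_episodes(), empty_deaths())
        return derive_per_protocol(
            cohort, rx, adverse if adverse is not None else empty_adverse())

    def test_discontinuation_183_days_after_last_prescription(self):
        # continuous monthly issues up to day 300, then nothing
        entries = [(1, pd.Timestamp(IDX) + pd.Timedelta(days=d), "olanzapine",
                    10.0, False, False) for d in range(0, 301, 30)]
        out = self._with_outcomes(entries)
        # censor day 300 + 183 = 483 -> month floor(483/30.4375)+1 = 16
        assert out.loc[0, "pp_censor_month"] == 16
        assert out.loc[0, "pp_censor_reason"] == "discontinuation"

    def test_mid_followup_gap_censors_at_first_lapse(self):
        """A >183-day gap inside the record censors at (last issue before
        the gap) + 183, not at the final prescription."""
        out = self._with_outcomes(
            [(1, IDX, "olanzapine", 10.0, False, False),
             (1, pd.Timestamp(IDX) + pd.Timedelta(days=300), "olanzapine",
              10.0, False, False)])
        assert out.loc[0, "pp_censor_month"] == 7   # day 183
        assert out.loc[0, "pp_censor_reason"] == "discontinuation"

    def test_switch_with_adverse_reaction_code_is_exempt(self):
        switch_day = pd.Timestamp(IDX) + pd.Timedelta(days=420)
        adverse = pd.DataFrame([{"patient_id": 1,
                                 "date": switch_day + pd.Timedelta(days=10),
                                 "drug": "olanzapine"}])
        entries = [(1, pd.Timestamp(IDX) + pd.Timedelta(days=d), "olanzapine",
                    10.0, False, False) for d in range(0, 391, 30)]
        out = self._with_outcomes(
            entries + [(1, switch_day, "aripiprazole", 10.0, False, False)],
            adverse=adverse)
        assert out.loc[0, "pp_exempted"]
        assert out.loc[0, "pp_censor_reason"] != "switch"
        # only the (post-switch) discontinuation gap may censor later
        assert out.loc[0, "pp_censor_month"] is pd.NA or \
            out.loc[0, "pp_censor_reason"] == "discontinuation"

    def test_continuous_prescribing_never_censors(self):
        entries = [(1, pd.Timestamp(IDX) + pd.Timedelta(days=30 * k),
                    "olanzapine", 10.0, False, False) for k in range(62)]
        out = self._with_outcomes(entries)
        assert pd.isna(out.loc[0, "pp_censor_month"])

    def test_new_drug_while_original_active_is_addition(self):
        out = self._with_outcomes(
            [(1, IDX, "olanzapine", 10.0, False, False),
             (1, pd.Timestamp(IDX) + pd.Timedelta(days=100), "olanzapine",
              10.0, False, False),
             (1, pd.Timestamp(IDX) + pd.Timedelta(days=130), "risperidone",
              4.0, False, False)])
        assert out.loc[0, "pp_censor_reason"] == "addition"
        assert out.loc[0, "pp_censor_month"] == 5   # day 130

    def test_pp_followup_within_itt_followup(self, cohort):
        itt_end = (cohort["itt_event_month"].fillna(0)
                   + cohort["itt_censor_month"].fillna(0)).astype(int)
        pp = cohort["pp_censor_month"]
        assert (pp.dropna() <= itt_end[pp.notna()]).all()


class TestDoseConversion:
    @pytest.mark.parametrize("drug,dose,expected", [
        ("olanzapine", 10.0, 10.0),
        ("risperidone", 5.0, 10.0),
        ("aripiprazole", 30.0, 20.0),
        ("quetiapine", 400.0, 10.0),
    ])
    def test_ddd_table_lookup(self, drug, dose, expected):
        assert olanzapine_equivalent_dose(drug, dose) == \
            pytest.approx(expected)

    def test_unknown_drug_and_nonpositive_dose_rejected(self):
        with pytest.raises(KeyError):
            olanzapine_equivalent_dose("clozapine", 100.0)
        with pytest.raises(ValueError):
            olanzapine_equivalent_dose("olanzapine", 0.0)


def brute_force_itt(patient_id, index_date, episodes, deaths, horizon=60):
    """Day-level reference: scan raw records chronologically and apply the
    outcome rules directly."""
    idx = pd.Timestamp(index_date)
    horizon_days = horizon * MONTH_DAYS
    ep = episodes[episodes["patient_id"] == patient_id]
    events = []
    for _, r in ep.iterrows():
        d = (pd.Timestamp(r["admission_date"]) - idx).days
        code = str(r["primary_icd10"])
        if 0 <= d < horizon_days:
            if code.startswith("I21"):
                events.append((d, "mi"))
            elif code[:3] in {"I60", "I61", "I62", "I63", "I64"}:
                events.append((d, "stroke"))
    de = deaths[deaths["patient_id"] == patient_id]
    death = None
    for _, r in de.iterrows():
        d = (pd.Timestamp(r["date"]) - idx).days
        if death is None or d < death[0]:
            death = (d, str(r["underlying_cause_icd10"]).startswith("I"))
    if death is not None and death[1] and death[0] < horizon_days:
        events.append((death[0], "cv_death"))
    events.sort()
    first = events[0] if events else None
    if first is not None:
        day, typ = first
        if typ != "cv_death" and death is not None and \
                0 <= death[0] - day <= 28:
            typ = "cv_death"
        month = min(int(day // MONTH_DAYS) + 1, 60)
        # a non-CV death in an earlier month pre-empts the event
        if death is not None and not death[1] and death[0] < horizon_days:
            dmonth = min(int(death[0] // MONTH_DAYS) + 1, 60)
            if dmonth < month and not (0 <= death[0] - day <= 28):
                return (None, dmonth, "noncv_death")
        return ((month, typ), None, None)
    if death is not None and not death[1] and death[0] < horizon_days:
        return (None, min(int(death[0] // MONTH_DAYS) + 1, 60), "noncv_death")
    return (None, 60, "horizon")


def test_day_level_brute_force_oracle_agrees(raw_tables, cohort):
    rng = np.random.default_rng(99)
    sample = rng.choice(cohort.index, size=50, replace=False)
    for i in sample:
        row = cohort.loc[i]
        ev, cen, reason = brute_force_itt(row["patient_id"], row["index_date"],
                                          raw_tables.episodes,
                                          raw_tables.deaths)
        if ev is not None:
            assert row["itt_event_month"] == ev[0], row["patient_id"]
            assert row["itt_event_type"] == ev[1], row["patient_id"]
        else:
            assert row["itt_censor_month"] == cen
            assert row["itt_censor_reason"] == reason
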