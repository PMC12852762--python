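"""Trial-emulation cohort construction.

Applies eligibility at the index date (first study-drug prescription inside
the recruitment window), derives intention-to-treat follow-up from hospital
episodes and death registrations, and derives per-protocol censoring from
the prescription record, producing one analysis row per patient.

Month convention: month index = floor(days since index / 30.4375) + 1,
capped at 60; an event recorded in a month counts before that month's
censoring (event-first tie-break, the conservative discrete-time choice).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .config import (ARMS, DDD_MG, HORIZON_MONTHS, MONTH_DAYS,
                     EligibilityCriteria)
from .simulate import RawTables, month_from_day

__all__ = [
    "apply_eligibility",
    "derive_outcomes",
    "derive_per_protocol",
    "olanzapine_equivalent_dose",
    "build_cohort",
]

HORIZON_DAYS = HORIZON_MONTHS * MONTH_DAYS

#: Flow-diagram order of the exclusion criteria.
EXCLUSION_ORDER = (
    "index_outside_window", "age", "registration_under_6m", "prior_history",
    "not_linkage_eligible", "co_prescription_at_index", "lai_prior_90d",
    "pro_re_nata_first", "no_smi_at_index",
)


def olanzapine_equivalent_dose(drug: str, daily_dose_mg) -> float | np.ndarray:
    """Convert a daily dose to its olanzapine equivalent via WHO defined
    daily doses: dose / DDD(drug) x DDD(olanzapine)."""
    if drug not in DDD_MG:
        raise KeyError(f"unknown study drug {drug!r}")
    dose = np.asarray(daily_dose_mg, float)
    if (dose <= 0).any():
        raise ValueError("daily dose must be positive")
    out = dose / DDD_MG[drug] * DDD_MG["olanzapine"]
    return float(out) if out.ndim == 0 else out


def _is_mi(codes: pd.Series) -> pd.Series:
    return codes.astype(str).str.startswith("I21")


def _is_stroke(codes: pd.Series) -> pd.Series:
    s = codes.astype(str)
    return s.str.match(r"I6[0-4]")


def apply_eligibility(tables: RawTables,
                      criteria: EligibilityCriteria | None = None
                      ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the eligibility rules and return (cohort skeleton, exclusion
    tally).

    The cohort skeleton has one row per included patient with index date,
    assigned arm, baseline covariates and olanzapine-equivalent starting
    dose; follow-up fields are filled by :func:`derive_outcomes` /
    :func:`derive_per_protocol`.  The tally maps each criterion, in
    flow-diagram order, to the number of candidates it removed; criteria are
    applied sequentially so counts are disjoint and sum (with the included
    count) to the candidate count.
    """
    criteria = criteria or EligibilityCriteria()
    rx = tables.prescriptions
    study_rx = rx[rx["drug"].isin(ARMS)]
    if study_rx.empty:
        warnings.warn("empty prescriptions table: cohort is empty")
        return pd.DataFrame(), {k: 0 for k in EXCLUSION_ORDER}

    # index date = first study-drug prescription (patients are eligible once)
    first = study_rx.loc[study_rx.groupby("patient_id")["date"].idxmin(),
                         ["patient_id", "date"]]
    first = first.rename(columns={"date": "index_date"})
    index_rx = study_rx.merge(first, on="patient_id")
    index_rx = index_rx[index_rx["date"] == index_rx["index_date"]]

    df = tables.patients.merge(first, on="patient_id", how="inner")
    n_candidates = len(df)
    tally: dict[str, int] = {}

    w0 = pd.Timestamp(criteria.recruitment_window[0])
    w1 = pd.Timestamp(criteria.recruitment_window[1])
    idx = pd.to_datetime(df["index_date"])
    keep = (idx >= w0) & (idx <= w1)
    tally["index_outside_window"] = int((~keep).sum())
    df, idx = df[keep], idx[keep]

    age = idx.dt.year - df["birth_year"]
    lo, hi = criteria.age_range
    keep = (age >= lo) & (age <= hi)
    tally["age"] = int((~keep).sum())
    df, idx, age = df[keep], idx[keep], age[keep]
    df = df.assign(age=age)

    reg = pd.to_datetime(df["registration_date"])
    keep = (idx - reg).dt.days >= criteria.registration_lookback_days
    keep &= reg.notna()
    tally["registration_under_6m"] = int((~keep).sum())
    df, idx = df[keep], idx[keep]

    # prior MI/stroke/dementia: patient-level history flag plus any
    # qualifying hospital episode before index
    ep = tables.episodes.merge(df[["patient_id", "index_date"]], on="patient_id")
    prior_ev = ep[(pd.to_datetime(ep["admission_date"])
                   < pd.to_datetime(ep["index_date"]))
                  & (_is_mi(ep["primary_icd10"]) | _is_stroke(ep["primary_icd10"]))]
    flagged = set(prior_ev["patient_id"])
    keep = ~(df["history_mi_stroke_dementia"].astype(bool)
             | df["patient_id"].isin(flagged))
    tally["prior_history"] = int((~keep).sum())
    df, idx = df[keep], idx[keep]

    if criteria.require_linkage:
        keep = df["practice_linkage_eligible"].astype(bool)
        tally["not_linkage_eligible"] = int((~keep).sum())
        df, idx = df[keep], idx[keep]
    else:
        tally["not_linkage_eligible"] = 0

    # monotherapy at index: no second study drug prescribed on the index date
    at_index = index_rx[index_rx["patient_id"].isin(df["patient_id"])]
    n_drugs = at_index.groupby("patient_id")["drug"].nunique()
    poly = set(n_drugs[n_drugs > 1].index)
    keep = ~df["patient_id"].isin(poly)
    tally["co_prescription_at_index"] = int((~keep).sum())
    df, idx = df[keep], idx[keep]

    lai = rx[rx["long_acting_injectable"].astype(bool)].merge(
        df[["patient_id", "index_date"]], on="patient_id")
    lai_days = (pd.to_datetime(lai["index_date"])
                - pd.to_datetime(lai["date"])).dt.days
    lai_ids = set(lai.loc[(lai_days >= 0)
                          & (lai_days <= criteria.lai_lookback_days),
                          "patient_id"])
    keep = ~df["patient_id"].isin(lai_ids)
    tally["lai_prior_90d"] = int((~keep).sum())
    df, idx = df[keep], idx[keep]

    if criteria.exclude_pro_re_nata:
        prn_ids = set(index_rx.loc[index_rx["pro_re_nata"].astype(bool),
                                   "patient_id"])
        keep = ~df["patient_id"].isin(prn_ids)
        tally["pro_re_nata_first"] = int((~keep).sum())
        df, idx = df[keep], idx[keep]
    else:
        tally["pro_re_nata_first"] = 0

    smi = pd.to_datetime(df["smi_diagnosis_date"])
    if criteria.inclusive_smi:
        keep = smi.notna()
    else:
        keep = smi.notna() & ((smi - idx).dt.days
                              <= criteria.smi_grace_days_after_index)
    tally["no_smi_at_index"] = int((~keep).sum())
    df = df[keep]

    assert sum(tally.values()) + len(df) == n_candidates

    # assigned arm + starting dose from the index prescription
    arm_rx = index_rx[index_rx["patient_id"].isin(df["patient_id"])]
    arm_rx = arm_rx.sort_values(["patient_id", "drug"]).groupby(
        "patient_id", as_index=False).first()
    cohort = df.merge(arm_rx[["patient_id", "drug", "daily_dose_mg"]],
                      on="patient_id")
    cohort = cohort.rename(columns={"drug": "arm"})
    ddd = cohort["arm"].map(DDD_MG)
    cohort["starting_dose_olz_equiv"] = (
        cohort["daily_dose_mg"] / ddd * DDD_MG["olanzapine"])
    drop = ["birth_year", "registration_date", "practice_linkage_eligible",
            "history_mi_stroke_dementia", "daily_dose_mg"]
    cohort = cohort.drop(columns=[c for c in drop if c in cohort.columns])
    cohort["index_date"] = pd.to_datetime(cohort["index_date"])
    return cohort.reset_index(drop=True), tally


def derive_outcomes(cohort: pd.DataFrame, episodes: pd.DataFrame,
                    deaths: pd.DataFrame,
                    horizon: int = HORIZON_MONTHS) -> pd.DataFrame:
    """Fill intention-to-treat follow-up for the MACE composite and its
    components.

    MI = primary ICD-10 I21*; stroke = I60*-I64*; cardiovascular death =
    underlying cause in chapter I; a death within 28 days of an MI/stroke
    episode reclassifies that event as cardiovascular death.  Follow-up is
    censored at the earlier of non-cardiovascular death and the horizon.
    """
    out = cohort.copy()
    n = len(out)
    idx_date = pd.to_datetime(out["index_date"])
    pid_to_row = pd.Series(np.arange(n), index=out["patient_id"])

    ep = episodes.merge(out[["patient_id", "index_date"]], on="patient_id")
    ep_day = (pd.to_datetime(ep["admission_date"])
              - pd.to_datetime(ep["index_date"])).dt.days
    is_mi, is_st = _is_mi(ep["primary_icd10"]), _is_stroke(ep["primary_icd10"])
    if ((ep_day < 0) & (is_mi | is_st)).any():
        raise ValueError("MACE episode before index date: prevalent event "
                         "leaked through eligibility")

    def first_day(mask):
        days = np.full(n, np.inf)
        sub = ep[mask & (ep_day >= 0) & (ep_day < HORIZON_DAYS)]
        if len(sub):
            m = sub.assign(day=ep_day[sub.index]).groupby("patient_id")["day"].min()
            days[pid_to_row[m.index].to_numpy()] = m.to_numpy()
        return days

    mi_day = first_day(is_mi)
    st_day = first_day(is_st)

    de = deaths.merge(out[["patient_id", "index_date"]], on="patient_id")
    de_day = (pd.to_datetime(de["date"])
              - pd.to_datetime(de["index_date"])).dt.days
    death_day = np.full(n, np.inf)
    cv_cause = np.zeros(n, bool)
    if len(de):
        d = de.assign(day=de_day).sort_values("day").groupby(
            "patient_id", as_index=False).first()
        rows = pid_to_row[d["patient_id"]].to_numpy()
        death_day[rows] = d["day"].to_numpy()
        cv_cause[rows] = d["underlying_cause_icd10"].astype(str).str.startswith("I")

    # 28-day fatality rule, per component episode
    ep_first = np.minimum(mi_day, st_day)
    with np.errstate(invalid="ignore"):
        lag = death_day - ep_first
    fatal = np.isfinite(lag) & (lag >= 0) & (lag <= 28)
    # pure CV death (chapter-I underlying cause), at the death month
    horizon_day = horizon * MONTH_DAYS
    cv_death_day = np.where(fatal & np.isfinite(ep_first), ep_first,
                            np.where(cv_cause, death_day, np.inf))
    noncv_death_day = np.where(~cv_cause & ~fatal, death_day, np.inf)

    event_day = np.minimum.reduce([mi_day, st_day, cv_death_day])
    has_event = np.isfinite(event_day) & (event_day < horizon_day)
    event_month = np.zeros(n, int)
    event_month[has_event] = month_from_day(event_day[has_event])
    ev_type = np.full(n, None, dtype=object)
    ev_type[has_event] = "cv_death"
    ev_type[has_event & (event_day == st_day) & ~fatal] = "stroke"
    ev_type[has_event & (event_day == mi_day) & ~fatal] = "mi"

    has_cens = np.isfinite(noncv_death_day) & (noncv_death_day < horizon_day)
    cens_month = np.full(n, horizon)
    cens_month[has_cens] = month_from_day(noncv_death_day[has_cens])
    # event-first rule: an event in the censoring month still counts
    event_wins = has_event & (event_month <= cens_month)

    out["itt_event_month"] = pd.array(
        np.where(event_wins, event_month, np.nan), dtype="Int64")
    out["itt_event_type"] = np.where(event_wins, ev_type, None)
    out["itt_censor_month"] = pd.array(
        np.where(event_wins, np.nan, cens_month), dtype="Int64")
    out["itt_censor_reason"] = np.where(
        event_wins, None, np.where(has_cens, "noncv_death", "horizon"))

    # component-specific follow-up: event at first component incidence,
    # censoring at any other-cause death or the horizon
    any_death = np.minimum(cv_death_day, noncv_death_day)
    for comp, day in (("mi", np.where(fatal, np.inf, mi_day)),
                      ("stroke", np.where(fatal, np.inf, st_day)),
                      ("cv_death", cv_death_day)):
        has_ev = np.isfinite(day) & (day < horizon_day)
        ev_m = np.zeros(n, int)
        ev_m[has_ev] = month_from_day(day[has_ev])
        other_death = np.where(has_ev & (any_death >= day), np.inf, any_death)
        has_cn = np.isfinite(other_death) & (other_death < horizon_day)
        cn_m = np.full(n, horizon)
        cn_m[has_cn] = month_from_day(other_death[has_cn])
        wins = has_ev & (ev_m <= cn_m)
        out[f"{comp}_event_month"] = pd.array(
            np.where(wins, ev_m, np.nan), dtype="Int64")
        out[f"{comp}_censor_month"] = pd.array(
            np.where(wins, np.nan, cn_m), dtype="Int64")
    return out


def derive_per_protocol(cohort: pd.DataFrame, prescriptions: pd.DataFrame,
                        adverse_reactions: pd.DataFrame,
                        discontinuation_gap_days: int = 183) -> pd.DataFrame:
    """Fill per-protocol censoring fields.

    Follow-up under the "initiate and continue" strategy is censored at the
    earliest of: prescription of another study antipsychotic (addition if
    the original is still active, i.e. within the discontinuation gap of its
    last issue, switch otherwise), discontinuation (gap days after the last
    original-drug prescription), deregistration, or the practice's last
    data-collection date.  No censoring applies when an adverse-reaction
    code for the original drug is recorded within 30 days of the strategy
    deviation: treatment change is then strategy-consistent and the patient
    is exempt from deviation-based censoring.
    """
    out = cohort.copy()
    n = len(out)
    gap = discontinuation_gap_days
    key = out[["patient_id", "index_date", "arm"]]
    rx = prescriptions.merge(key, on="patient_id")
    rx["day"] = (pd.to_datetime(rx["date"])
                 - pd.to_datetime(rx["index_date"])).dt.days
    rx = rx[rx["day"] >= 0]
    pid_to_row = pd.Series(np.arange(n), index=out["patient_id"])

    orig = rx[rx["drug"] == rx["arm"]].drop_duplicates(
        ["patient_id", "day"]).sort_values(["patient_id", "day"])
    prev = orig.groupby("patient_id")["day"].shift()
    gap_break = (orig["day"] - prev) > gap
    disc_day = np.full(n, np.inf)
    br = orig[gap_break]
    if len(br):
        first_gap = (prev[gap_break.index][gap_break] + gap).groupby(
            br["patient_id"]).min()
        disc_day[pid_to_row[first_gap.index].to_numpy()] = first_gap.to_numpy()
    last = orig.groupby("patient_id")["day"].max()
    tail = last + gap
    rows = pid_to_row[tail.index].to_numpy()
    disc_day[rows] = np.minimum(disc_day[rows], tail.to_numpy())

    other = rx[(rx["drug"] != rx["arm"]) & rx["drug"].isin(ARMS)
               & (rx["day"] > 0)]
    other_first = other.groupby("patient_id")["day"].min()
    other_day = np.full(n, np.inf)
    rows_o = pid_to_row[other_first.index].to_numpy()
    other_day[rows_o] = other_first.to_numpy()
    # addition vs switch: is the original drug still active at that day?
    last_before = np.full(n, -np.inf)
    lb = orig.merge(other_first.rename("oday"), on="patient_id")
    lb = lb[lb["day"] < lb["oday"]].groupby("patient_id")["day"].max()
    if len(lb):
        last_before[pid_to_row[lb.index].to_numpy()] = lb.to_numpy()
    is_addition = (other_day - last_before) <= gap

    dereg = (pd.to_datetime(out["deregistration_date"])
             - pd.to_datetime(out["index_date"])).dt.days.to_numpy(float)
    dereg = np.where(np.isnan(dereg), np.inf, dereg)
    lastcoll = (pd.to_datetime(out["last_collection_date"])
                - pd.to_datetime(out["index_date"])).dt.days.to_numpy(float)
    lastcoll = np.where(np.isnan(lastcoll), np.inf, lastcoll)

    # deviation-based censoring, with the adverse-reaction exemption
    dev_day = np.minimum(np.where(other_day < disc_day, other_day, disc_day),
                         np.inf)
    dev_reason = np.where(
        other_day < disc_day,
        np.where(is_addition, "addition", "switch"), "discontinuation")
    adv = adverse_reactions.merge(key, on="patient_id")
    adv = adv[adv["drug"] == adv["arm"]]
    exempt = np.zeros(n, bool)
    # the 30-day exemption window anchors at the clinical change: the new
    # drug's first issue for switch/addition, the last original issue for
    # discontinuation (whose formal censor day sits a gap later)
    dev_anchor = np.where(other_day < disc_day, other_day, disc_day - gap)
    if len(adv):
        adv_day = (pd.to_datetime(adv["date"])
                   - pd.to_datetime(adv["index_date"])).dt.days
        adv = adv.assign(day=adv_day)
        rows_a = pid_to_row[adv["patient_id"]].to_numpy()
        rel = adv["day"].to_numpy() - dev_anchor[rows_a]
        hit = (rel >= 0) & (rel <= 30)
        exempt[rows_a[hit]] = True
    dev_day = np.where(exempt, np.inf, dev_day)

    admin_day = np.minimum(dereg, lastcoll)
    admin_reason = np.where(dereg <= lastcoll, "deregistration",
                            "last_collection")
    pp_day = np.minimum(dev_day, admin_day)
    pp_reason = np.where(dev_day <= admin_day, dev_reason, admin_reason)

    itt_end = out["itt_event_month"].fillna(0).to_numpy(int) \
        + out["itt_censor_month"].fillna(0).to_numpy(int)
    is_event = out["itt_event_month"].notna().to_numpy()
    # uncapped month index: censor days beyond the horizon never censor
    in_window = np.isfinite(pp_day) & (pp_day < HORIZON_DAYS)
    pp_month = np.zeros(n, int)
    pp_month[in_window] = month_from_day(pp_day[in_window])
    # events take precedence in their month; censoring-vs-censoring ties
    # resolve to the per-protocol reason
    active = (pp_month > 0) & np.where(is_event, pp_month < itt_end,
                                       pp_month <= itt_end)
    out["pp_censor_month"] = pd.array(
        np.where(active, pp_month, np.nan), dtype="Int64")
    out["pp_censor_reason"] = np.where(active, pp_reason, None)
    out["pp_exempted"] = exempt
    return out


def build_cohort(tables: RawTables,
                 criteria: EligibilityCriteria | None = None,
                 discontinuation_gap_days: int = 183
                 ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Eligibility + ITT outcomes + per-protocol censoring in one call."""
    skeleton, tally = apply_eligibility(tables, criteria)
    if skeleton.empty:
        return skeleton, tally
    cohort = derive_outcomes(skeleton, tables.episodes, tables.deaths)
    cohort = derive_per_protocol(cohort, tables.prescriptions,
                                 tables.adverse_reactions,
                                 discontinuation_gap_days)
    return cohort, tally
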