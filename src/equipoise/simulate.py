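"""Synthetic linked EHR cohort generator with known ground truth.

Emulates the structure of a UK primary-care database linked to hospital
admissions and death registrations: a patients table with baseline
covariates, primary-care prescription issues, hospital episodes with ICD-10
primary diagnoses, death registrations with an underlying cause, and rare
adverse-reaction codes.  Treatment assignment is confounded through a
softmax model on baseline covariates; events arise from a discrete monthly
hazard process over a 60-month horizon with a competing risk of
non-cardiovascular death; an adherence process emits switch / addition /
discontinuation prescription patterns; a MAR mechanism masks a configurable
covariate subset.

Time is simulated on a monthly grid (60 intervals of 30.4375 days) and
converted to calendar dates only at serialisation.  Every random component
draws from its own stream split from the master seed, with draws laid out
patient-major, so enlarging the cohort never perturbs earlier patients.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .config import (ARMS, DDD_MG, HORIZON_MONTHS, MONTH_DAYS,
                     CovariateSpec, SimulationConfig)

__all__ = [
    "RawTables",
    "generate_cohort",
    "apply_missingness",
    "true_marginal_risk",
    "month_from_day",
    "write_tables",
    "read_tables",
]

_COMORBIDITY_CODES = ["E11.9", "J44.9", "N18.3", "K76.0", "F10.2", "M06.9"]
_NONCV_DEATH_CAUSE = "C80.9"
_CV_DEATH_CAUSE = "I25.8"
_EVENT_CODES = {"mi": "I21.9", "stroke": "I63.9",
                "fatal_mi": "I21.9", "fatal_stroke": "I63.9"}


@dataclass
class RawTables:
    """Linked raw tables: the simulated analogue of primary-care records,
    hospital episodes and death registrations.

    ``truth`` carries the per-patient generating state (assigned arm, event
    months, deviation process) and ``complete_patients`` the pre-masking
    covariates; both exist only for oracle tests and are never read by the
    analysis pipeline.
    """

    patients: pd.DataFrame
    prescriptions: pd.DataFrame
    episodes: pd.DataFrame
    deaths: pd.DataFrame
    adverse_reactions: pd.DataFrame
    truth: pd.DataFrame | None = None
    complete_patients: pd.DataFrame | None = None


def month_from_day(days: np.ndarray | float) -> np.ndarray:
    """Map day offsets since index to 1-based month indices, capped at 60."""
    m = np.floor(np.asarray(days, float) / MONTH_DAYS).astype(int) + 1
    return np.minimum(m, HORIZON_MONTHS)


def _mid_month_day(month: np.ndarray) -> np.ndarray:
    """Day offset of the representative mid-month time point."""
    return np.rint((np.asarray(month, float) - 0.5) * MONTH_DAYS).astype(int)


def design_columns(df: pd.DataFrame, covariate_spec) -> dict[str, np.ndarray]:
    """Generator-side design columns: continuous standardised by the spec's
    loc/scale, binary as 0/1, categorical one-hot dropping the first level."""
    cols: dict[str, np.ndarray] = {}
    for cv in covariate_spec:
        x = df[cv.name].to_numpy()
        if cv.kind == "continuous":
            loc = cv.params["loc"]
            scale = cv.params.get("sd", cv.params.get("scale"))
            cols[cv.name] = (x.astype(float) - loc) / scale
        elif cv.kind == "binary":
            cols[cv.name] = x.astype(float)
        else:
            for lev in cv.params["levels"][1:]:
                cols[f"{cv.name}={lev}"] = (x == lev).astype(float)
    return cols


def _linear_predictor(cols: dict[str, np.ndarray], coefs: dict, n: int) -> np.ndarray:
    eta = np.full(n, float(coefs.get("_intercept", 0.0)))
    for name, beta in coefs.items():
        if name == "_intercept":
            continue
        if name not in cols:
            raise KeyError(f"coefficient on unknown design column {name!r}")
        eta = eta + beta * cols[name]
    return eta


def _stream_names(config: SimulationConfig) -> list[str]:
    return [f"cov:{cv.name}" for cv in config.covariate_spec] + [
        "index_date", "assignment", "mace", "mace_type", "fatal_lag", "death",
        "adherence_time", "adherence_type", "switch_target", "adverse",
        "adverse_lag", "comorbidity", "registration", "smi_date",
        "late_smi", "late_smi_lag", "prn",
    ] + [f"miss:{v}" for v in sorted(config.missingness_spec)]


def _streams(seed: int, names: list[str]) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {nm: np.random.Generator(np.random.PCG64(ch))
            for nm, ch in zip(names, children)}


def _draw_covariates(config: SimulationConfig, rngs) -> pd.DataFrame:
    n = config.n_patients
    data = {}
    for cv in config.covariate_spec:
        rng = rngs[f"cov:{cv.name}"]
        p = cv.params
        if cv.kind == "continuous":
            if p["dist"] == "normal":
                x = rng.standard_normal(n) * p["scale"] + p["loc"]
            elif p["dist"] == "gamma":
                x = rng.gamma(p["shape"], p["scale"], size=n)
            else:
                raise ValueError(f"unknown distribution {p['dist']!r}")
            lo, hi = p.get("clip", (-np.inf, np.inf))
            x = np.clip(x, lo, hi)
            if p.get("integer"):
                x = np.rint(x).astype(int)
            data[cv.name] = x
        elif cv.kind == "binary":
            data[cv.name] = (rng.random(n) < p["p"]).astype(int)
        else:
            u = rng.random(n)
            cum = np.cumsum(p["probs"])
            idx = np.searchsorted(cum, u, side="right").clip(0, len(cum) - 1)
            data[cv.name] = np.asarray(p["levels"], object)[idx]
    return pd.DataFrame(data)


def _first_hit_month(u: np.ndarray, hazard: np.ndarray) -> np.ndarray:
    """First month (1-based) where u < hazard, 0 if never.  Shapes (n, 60)."""
    hit = u < hazard
    any_hit = hit.any(axis=1)
    first = hit.argmax(axis=1) + 1
    return np.where(any_hit, first, 0)


def _ragged_months(start: np.ndarray, end: np.ndarray):
    """Patient index and month arrays for months start_i..end_i inclusive
    (empty when end < start)."""
    length = np.maximum(end - start + 1, 0)
    idx = np.repeat(np.arange(len(start)), length)
    offs = np.arange(length.sum()) - np.repeat(np.cumsum(length) - length, length)
    return idx, np.repeat(start, length) + offs


def generate_cohort(config: SimulationConfig) -> RawTables:
    """Generate the linked raw tables for one synthetic cohort.

    Deterministic given ``config.seed``; see the module docstring for the
    generating model.
    """
    n = config.n_patients
    rngs = _streams(config.seed, _stream_names(config))

    cov = _draw_covariates(config, rngs)
    cols = design_columns(cov, config.covariate_spec)
    arms = list(config.arms)

    # --- treatment assignment: softmax over per-arm linear scores ---------
    scores = np.column_stack(
        [_linear_predictor(cols, config.ps_coefficients[a], n) for a in arms])
    scores -= scores.max(axis=1, keepdims=True)
    probs = np.exp(scores)
    probs /= probs.sum(axis=1, keepdims=True)
    u = rngs["assignment"].random(n)
    arm_idx = (u[:, None] >= np.cumsum(probs, axis=1)).sum(axis=1)
    arm = np.asarray(arms, object)[arm_idx]

    # --- index dates ------------------------------------------------------
    w0 = np.datetime64(config.recruitment_window[0])
    w1 = np.datetime64(config.recruitment_window[1])
    span = int((w1 - w0) / np.timedelta64(1, "D"))
    index_date = w0 + rngs["index_date"].integers(0, span + 1, size=n)

    # --- monthly event processes ------------------------------------------
    cov_eff = _linear_predictor(cols, config.log_hazard_effects["covariates"], n)
    arm_eff = np.asarray(
        [config.log_hazard_effects["arms"][a] for a in arms])[arm_idx]
    with np.errstate(divide="ignore"):
        base = logit(np.clip(config.baseline_hazard, 1e-300, 1 - 1e-15))
    hazard = expit(base[None, :] + (cov_eff + arm_eff)[:, None])
    hazard = np.where(config.baseline_hazard[None, :] == 0.0, 0.0, hazard)

    mace_month = _first_hit_month(rngs["mace"].random((n, HORIZON_MONTHS)), hazard)
    dmat = np.broadcast_to(config.noncv_death_hazard[None, :], (n, HORIZON_MONTHS))
    death_month = _first_hit_month(rngs["death"].random((n, HORIZON_MONTHS)), dmat)

    # resolve competing processes; ties go to the MACE event (event-first rule)
    has_mace = (mace_month > 0) & ((death_month == 0) | (mace_month <= death_month))
    has_noncv = (death_month > 0) & ~has_mace
    mace_month = np.where(has_mace, mace_month, 0)
    noncv_month = np.where(has_noncv, death_month, 0)

    type_labels = list(config.mace_type_probs)
    type_cum = np.cumsum([config.mace_type_probs[t] for t in type_labels])
    t_u = rngs["mace_type"].random(n)
    mace_type = np.asarray(type_labels, object)[
        np.searchsorted(type_cum, t_u, side="right").clip(0, len(type_labels) - 1)]
    mace_type = np.where(has_mace, mace_type, None)
    fatal_lag = rngs["fatal_lag"].integers(0, 29, size=n)

    # --- adherence / strategy deviation -----------------------------------
    adh = config.adherence_params
    base_p = np.asarray([adh["monthly_deviation"][a] for a in arms])[arm_idx]
    with np.errstate(divide="ignore"):
        dev_logit = logit(np.clip(base_p, 1e-12, 1 - 1e-12))
    dev_logit = dev_logit + _linear_predictor(
        {**cols}, {k: v for k, v in adh.get("covariate_log_odds", {}).items()}, n)
    p_dev = np.where(base_p == 0.0, 0.0, expit(dev_logit))
    dev_u = rngs["adherence_time"].random((n, HORIZON_MONTHS))
    dev_u[:, 0] = 1.0   # monotherapy at index: no deviation in month 1
    dev_month = _first_hit_month(dev_u, p_dev[:, None])
    tp = adh["type_probs"]
    t_cum = np.cumsum([tp["switch"], tp["addition"], tp["discontinuation"]])
    dev_type = np.asarray(["switch", "addition", "discontinuation"], object)[
        np.searchsorted(t_cum, rngs["adherence_type"].random(n),
                        side="right").clip(0, 2)]
    # switch / addition target: a different study drug
    other = rngs["switch_target"].integers(0, 3, size=n)
    new_idx = (arm_idx + 1 + other) % 4
    new_drug = np.asarray(arms, object)[new_idx]

    # month after which no prescriptions are issued (death stops them)
    death_any = np.where(
        has_mace & np.isin(mace_type, ["cv_death", "fatal_mi", "fatal_stroke"]),
        mace_month, 0)
    death_any = np.where(has_noncv, noncv_month, death_any)
    rx_end = np.where(death_any > 0, death_any, HORIZON_MONTHS)
    dev_active = (dev_month > 0) & (dev_month <= rx_end)
    dev_month = np.where(dev_active, dev_month, 0)

    # --- patients table ----------------------------------------------------
    smi_lag = rngs["smi_date"].integers(0, 5841, size=n)   # up to ~16 y before
    late = rngs["late_smi"].random(n) < config.late_smi_prob
    late_lag = rngs["late_smi_lag"].integers(31, 366, size=n)
    smi_date = np.where(late, index_date + late_lag, index_date - smi_lag)
    reg_lag = 183 + rngs["registration"].integers(0, 1826, size=n)
    index_year = index_date.astype("datetime64[Y]").astype(int) + 1970
    patients = pd.DataFrame({
        "patient_id": np.arange(1, n + 1),
        "birth_year": index_year - cov["age"].to_numpy(),
        "registration_date": index_date - reg_lag,
        "practice_linkage_eligible": np.ones(n, bool),
        "smi_diagnosis_date": smi_date.astype("datetime64[D]"),
        "smi_diagnosis_type": cov["smi_diagnosis"].to_numpy(),
        "history_mi_stroke_dementia": np.zeros(n, bool),
        "deregistration_date": np.full(n, np.datetime64("NaT", "D")),
        "last_collection_date": np.full(n, np.datetime64("2021-03-31")),
    })
    for c in cov.columns:
        # age is derived from birth_year downstream; the starting dose lives
        # on the index prescription, not the patients table
        if c not in ("age", "starting_dose_olz_equiv"):
            patients[c] = cov[c].to_numpy()

    # --- prescriptions ------------------------------------------------------
    dose_equiv = cov["starting_dose_olz_equiv"].to_numpy(float)
    prn = rngs["prn"].random(n) < config.prn_first_prob

    orig_end = np.where(dev_month > 0,
                        np.where(dev_type == "switch", dev_month - 1,
                                 np.where(dev_type == "discontinuation",
                                          dev_month, rx_end)),
                        rx_end)
    orig_end = np.minimum(orig_end, rx_end)
    i1, m1 = _ragged_months(np.ones(n, int), orig_end)
    second_start = np.where(dev_month > 0, dev_month, 1)
    second_end = np.where(
        (dev_month > 0) & np.isin(dev_type, ["switch", "addition"]), rx_end, 0)
    i2, m2 = _ragged_months(second_start, second_end)

    ddd = np.asarray([DDD_MG[a] for a in arms])

    def _rx_frame(idx, month, drug_idx):
        return pd.DataFrame({
            "patient_id": idx + 1,
            "date": index_date[idx]
            + np.rint((month - 1) * MONTH_DAYS).astype(int),
            "drug": np.asarray(arms, object)[drug_idx],
            "daily_dose_mg": dose_equiv[idx] * ddd[drug_idx] / DDD_MG["olanzapine"],
            "pro_re_nata": np.zeros(len(idx), bool),
            "long_acting_injectable": np.zeros(len(idx), bool),
        })

    rx1 = _rx_frame(i1, m1, arm_idx[i1])
    rx1.loc[(m1 == 1) & prn[i1], "pro_re_nata"] = True
    rx2 = _rx_frame(i2, m2, new_idx[i2])
    prescriptions = pd.concat([rx1, rx2], ignore_index=True)
    prescriptions = prescriptions.sort_values(
        ["patient_id", "date", "drug"], kind="stable").reset_index(drop=True)

    # --- episodes (MACE + comorbidity onsets) ------------------------------
    ep_frames = []
    ev = has_mace & np.isin(mace_type, list(_EVENT_CODES))
    if ev.any():
        ep_frames.append(pd.DataFrame({
            "patient_id": np.flatnonzero(ev) + 1,
            "admission_date": index_date[ev] + _mid_month_day(mace_month[ev]),
            "primary_icd10": [_EVENT_CODES[t] for t in mace_type[ev]],
        }))
    com_u = rngs["comorbidity"].random((n, HORIZON_MONTHS))
    ci, ct = np.nonzero(com_u < config.comorbidity_onset_prob)
    if len(ci):
        rank = np.zeros(len(ci), int)
        _, starts, counts = np.unique(ci, return_index=True, return_counts=True)
        for s, c in zip(starts, counts):
            rank[s:s + c] = np.arange(c)
        ep_frames.append(pd.DataFrame({
            "patient_id": ci + 1,
            "admission_date": index_date[ci] + _mid_month_day(ct + 1),
            "primary_icd10": [
                _COMORBIDITY_CODES[r % len(_COMORBIDITY_CODES)] for r in rank],
        }))
    episodes = (pd.concat(ep_frames, ignore_index=True) if ep_frames
                else pd.DataFrame(columns=["patient_id", "admission_date",
                                           "primary_icd10"]))
    episodes = episodes.sort_values(
        ["patient_id", "admission_date"], kind="stable").reset_index(drop=True)

    # --- deaths -------------------------------------------------------------
    death_rows = []
    cvd = has_mace & (mace_type == "cv_death")
    if cvd.any():
        death_rows.append(pd.DataFrame({
            "patient_id": np.flatnonzero(cvd) + 1,
            "date": index_date[cvd] + _mid_month_day(mace_month[cvd]),
            "underlying_cause_icd10": _CV_DEATH_CAUSE,
        }))
    fatal = has_mace & np.isin(mace_type, ["fatal_mi", "fatal_stroke"])
    if fatal.any():
        death_rows.append(pd.DataFrame({
            "patient_id": np.flatnonzero(fatal) + 1,
            "date": index_date[fatal] + _mid_month_day(mace_month[fatal])
            + fatal_lag[fatal],
            "underlying_cause_icd10": [
                _EVENT_CODES[t] for t in mace_type[fatal]],
        }))
    if has_noncv.any():
        death_rows.append(pd.DataFrame({
            "patient_id": np.flatnonzero(has_noncv) + 1,
            "date": index_date[has_noncv] + _mid_month_day(noncv_month[has_noncv]),
            "underlying_cause_icd10": _NONCV_DEATH_CAUSE,
        }))
    deaths = (pd.concat(death_rows, ignore_index=True) if death_rows
              else pd.DataFrame(columns=["patient_id", "date",
                                         "underlying_cause_icd10"]))
    deaths = deaths.sort_values("patient_id", kind="stable").reset_index(drop=True)

    # --- adverse-reaction codes ---------------------------------------------
    has_dev = dev_month > 0
    adv = has_dev & (rngs["adverse"].random(n) < config.adverse_reaction_prob)
    adv_lag = rngs["adverse_lag"].integers(0, 31, size=n)
    if adv.any():
        adverse = pd.DataFrame({
            "patient_id": np.flatnonzero(adv) + 1,
            "date": index_date[adv]
            + np.rint((dev_month[adv] - 1) * MONTH_DAYS).astype(int)
            + adv_lag[adv],
            "drug": arm[adv],
        })
    else:
        adverse = pd.DataFrame(columns=["patient_id", "date", "drug"])

    truth = pd.DataFrame({
        "patient_id": np.arange(1, n + 1),
        "arm": arm,
        "index_date": index_date,
        "mace_month": mace_month,
        "mace_type": mace_type,
        "noncv_death_month": noncv_month,
        "deviation_month": dev_month,
        "deviation_type": np.where(has_dev, dev_type, None),
        "prn_first": prn,
        "late_smi": late,
    })
    for c in cov.columns:
        truth[c] = cov[c].to_numpy()

    return RawTables(patients=patients, prescriptions=prescriptions,
                     episodes=episodes, deaths=deaths,
                     adverse_reactions=adverse, truth=truth,
                     complete_patients=patients.copy())


_PROTECTED_FIELDS = {"patient_id", "arm", "mace_month", "mace_type",
                     "noncv_death_month", "registration_date",
                     "smi_diagnosis_date", "practice_linkage_eligible"}


def apply_missingness(tables: RawTables, config: SimulationConfig) -> RawTables:
    """Mask covariate cells missing-at-random per ``config.missingness_spec``.

    The missingness probability of each target covariate is a logistic
    function of always-observed fields only, so the mechanism is MAR by
    construction.  The pre-masking patients table is retained on
    ``complete_patients`` for recovery tests.
    """
    spec = config.missingness_spec
    cov_names = {cv.name for cv in config.covariate_spec}
    for v in spec:
        if v in _PROTECTED_FIELDS or v not in cov_names | {"starting_dose_olz_equiv"}:
            raise ValueError(
                f"missingness may target baseline covariates only, not {v!r}")
        for pred in spec[v].get("predictors", {}):
            base = pred.split("=")[0]
            if base in spec:
                raise ValueError(
                    f"MAR predictor {pred!r} is itself subject to missingness")

    rngs = _streams(config.seed, _stream_names(config))

    patients = tables.patients.copy()
    complete = tables.complete_patients
    if complete is None:
        complete = tables.patients.copy()
    n = len(patients)
    # design columns for MAR predictors, from the complete table; age lives
    # on the truth frame (patients stores birth_year)
    cdf = complete.copy()
    for cv in config.covariate_spec:
        if cv.name not in cdf.columns:
            if tables.truth is None:
                raise ValueError(
                    "apply_missingness requires generator output (the truth "
                    f"frame carries the {cv.name!r} covariate)")
            cdf[cv.name] = tables.truth[cv.name].to_numpy()
    cols = design_columns(cdf, config.covariate_spec)

    for v in sorted(spec):
        mdl = spec[v]
        eta = np.full(n, float(mdl.get("intercept", 0.0)))
        for pred, beta in mdl.get("predictors", {}).items():
            eta = eta + beta * cols[pred]
        p = expit(eta)
        if mdl.get("intercept", 0.0) == -np.inf:
            p = np.zeros(n)
        mask = rngs[f"miss:{v}"].random(n) < p
        if v == "starting_dose_olz_equiv":
            # dose lives on the index prescription and on the patients table
            if v in patients.columns:
                patients.loc[mask, v] = np.nan
            rx = tables.prescriptions
            first_idx = rx.groupby("patient_id")["date"].idxmin()
            masked_ids = set(patients.loc[mask, "patient_id"])
            sel = first_idx[first_idx.index.isin(masked_ids)]
            rx = rx.copy()
            rx.loc[sel.to_numpy(), "daily_dose_mg"] = np.nan
            tables = dataclasses.replace(tables, prescriptions=rx)
        elif patients[v].dtype == object:
            patients[v] = patients[v].where(~mask, None)
        else:
            patients[v] = patients[v].astype(float).where(~mask, np.nan)

    return dataclasses.replace(tables, patients=patients,
                               complete_patients=complete)


def true_marginal_risk(config: SimulationConfig, arm: str,
                       population: pd.DataFrame, horizon: int = HORIZON_MONTHS,
                       weights: np.ndarray | None = None) -> float:
    """Exact cumulative MACE incidence under "everyone assigned ``arm``".

    Averages 1 - prod_t (1 - h_t) over the supplied covariate sample
    (optionally weighted), treating non-cardiovascular death as censoring —
    the cause-specific estimand of the analysis pipeline.
    """
    if arm not in config.arms:
        raise ValueError(f"unknown arm {arm!r}")
    if not 0 <= horizon <= HORIZON_MONTHS:
        raise ValueError("horizon must lie in [0, 60]")
    if horizon == 0:
        return 0.0
    cols = design_columns(population, config.covariate_spec)
    n = len(population)
    eta = (_linear_predictor(cols, config.log_hazard_effects["covariates"], n)
           + config.log_hazard_effects["arms"][arm])
    h0 = config.baseline_hazard[:horizon]
    with np.errstate(divide="ignore"):
        base = logit(np.clip(h0, 1e-300, 1 - 1e-15))
    h = expit(base[None, :] + eta[:, None])
    h = np.where(h0[None, :] == 0.0, 0.0, h)
    risk = 1.0 - np.prod(1.0 - h, axis=1)
    if weights is None:
        return float(risk.mean())
    w = np.asarray(weights, float)
    return float(np.sum(w * risk) / np.sum(w))


def _config_to_jsonable(config: SimulationConfig) -> dict:
    def conv(x):
        if isinstance(x, np.ndarray):
            return x.tolist()
        if isinstance(x, (np.floating, np.integer)):
            return x.item()
        if isinstance(x, dict):
            return {str(k): conv(v) for k, v in x.items()}
        if isinstance(x, (list, tuple)):
            return [conv(v) for v in x]
        if isinstance(x, CovariateSpec):
            return {"name": x.name, "kind": x.kind, "params": conv(dict(x.params))}
        return x
    return {f.name: conv(getattr(config, f.name))
            for f in dataclasses.fields(config)}


def write_tables(tables: RawTables, outdir: str | Path,
                 config: SimulationConfig | None = None) -> None:
    """Write the four linked tables (+ adverse reactions) as CSV with
    ISO-8601 dates, and a JSON sidecar with the generating config and
    ground-truth per-arm risks."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name in ("patients", "prescriptions", "episodes", "deaths",
                 "adverse_reactions"):
        getattr(tables, name).to_csv(outdir / f"{name}.csv", index=False)
    if config is not None and tables.truth is not None:
        sidecar = {"config": _config_to_jsonable(config),
                   "true_marginal_risk_60m": {
                       a: true_marginal_risk(config, a, tables.truth)
                       for a in config.arms}}
        (outdir / "generation.json").write_text(json.dumps(sidecar, indent=2))


def read_tables(indir: str | Path) -> RawTables:
    indir = Path(indir)
    date_cols = {
        "patients": ["registration_date", "smi_diagnosis_date",
                     "deregistration_date", "last_collection_date"],
        "prescriptions": ["date"], "episodes": ["admission_date"],
        "deaths": ["date"], "adverse_reactions": ["date"]}
    frames = {}
    for name, dates in date_cols.items():
        df = pd.read_csv(indir / f"{name}.csv")
        for c in dates:
            if c in df.columns:
                df[c] = pd.to_datetime(df[c])
        frames[name] = df
    return RawTables(**frames)
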