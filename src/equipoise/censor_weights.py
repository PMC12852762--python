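"""Inverse-probability-of-censoring weights for the per-protocol estimand.

Per-protocol censoring (switch, addition, discontinuation, deregistration,
last data collection) is generally informative: patients who abandon the
strategy differ on covariates that also drive the outcome.  IPCW corrects
the induced selection by weighting each continuing person-month by the
inverse probability of having remained uncensored, stabilised by a
covariate-free (arm + time) numerator model:

    w_i(t) = prod_{u < t} [1 - pc_num(u)] / [1 - pc_den(u, X_i)]

so weights equal 1 in month 1 and accumulate only through positive monthly
ratios.  Weights are winsorised at a high percentile (99.5 by default) and
multiplied into the overlap weights downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import HORIZON_MONTHS, CensorModelSpec
from .glm import LogisticFit, fit_weighted_logistic
from .simulate import month_from_day
from .weights import build_design

__all__ = ["CensoringModel", "fit_censoring_model", "ipcw",
           "cumulative_comorbidity_counts"]

_ADMIN_REASONS = ("deregistration", "last_collection")
_MACE_STEMS = ("I21", "I60", "I61", "I62", "I63", "I64")


def cumulative_comorbidity_counts(cohort: pd.DataFrame,
                                  episodes: pd.DataFrame) -> np.ndarray:
    """(n_patients, 60) matrix: distinct non-MACE comorbidity categories
    recorded up to and including each follow-up month."""
    n = len(cohort)
    counts = np.zeros((n, HORIZON_MONTHS), int)
    ep = episodes.merge(cohort[["patient_id", "index_date"]], on="patient_id")
    if ep.empty:
        return counts
    codes = ep["primary_icd10"].astype(str)
    is_mace = codes.str.startswith(_MACE_STEMS)
    ep = ep[~is_mace]
    day = (pd.to_datetime(ep["admission_date"])
           - pd.to_datetime(ep["index_date"])).dt.days
    ep = ep.assign(day=day)
    ep = ep[(ep["day"] >= 0) & (ep["day"] < HORIZON_MONTHS * 30.4375)]
    if ep.empty:
        return counts
    ep["month"] = month_from_day(ep["day"].to_numpy())
    ep["cat"] = ep["primary_icd10"].astype(str).str[:3]
    firsts = ep.groupby(["patient_id", "cat"])["month"].min().reset_index()
    pid_to_row = pd.Series(np.arange(n), index=cohort["patient_id"])
    rows = pid_to_row[firsts["patient_id"]].to_numpy()
    onset = np.zeros((n, HORIZON_MONTHS), int)
    np.add.at(onset, (rows, firsts["month"].to_numpy() - 1), 1)
    return np.cumsum(onset, axis=1)


@dataclass
class CensoringModel:
    """Fitted monthly censoring models (stabilisation numerator and
    covariate denominator) for the per-protocol estimand."""

    spec: CensorModelSpec
    num_fit: LogisticFit | None
    den_fit: LogisticFit | None
    num_columns: list[str]
    den_columns: list[str]
    arms: tuple[str, ...]
    silent_arms: tuple[str, ...] = ()   # arms with zero censoring events
    covariates: tuple[str, ...] = ()
    design_X: np.ndarray | None = field(repr=False, default=None)


def _censor_indicator(pm: pd.DataFrame, include_admin: bool) -> np.ndarray:
    c = pm["pp_censored"].to_numpy(bool)
    if not include_admin:
        reason = pm["pp_censor_reason"].to_numpy(object)
        c = c & ~np.isin(reason, _ADMIN_REASONS)
    return c.astype(float)


def _num_den_design(pm, cohort, covariates, spec, comorbidity=None):
    arms = tuple(sorted(pd.unique(pm["arm"])))
    t = pm["t"].to_numpy(float)
    num_cols = [np.ones(len(pm)), t]
    num_names = ["_intercept", "t"]
    for a in arms[1:]:
        num_cols.append((pm["arm"] == a).to_numpy(float))
        num_names.append(f"arm={a}")
    Xn = np.column_stack(num_cols)

    rows = pm["row"].to_numpy()
    Xb, base_names = build_design(cohort, covariates, add_intercept=False)
    den_cols = [Xn, Xb[rows]]
    den_names = num_names + base_names
    if spec.covariate_set == "baseline_plus_timevarying":
        if comorbidity is None:
            raise ValueError("time-varying censoring model needs the "
                             "comorbidity count matrix")
        cc = comorbidity[rows, pm["t"].to_numpy() - 1].astype(float)
        den_cols.append(cc[:, None])
        den_names.append("cum_comorbidity")
    Xd = np.column_stack([np.asarray(c) if np.ndim(c) > 1 else
                          np.asarray(c)[:, None] for c in den_cols])
    return arms, Xn, num_names, Xd, den_names


def fit_censoring_model(pm: pd.DataFrame, cohort: pd.DataFrame,
                        covariates, spec: CensorModelSpec | None = None,
                        comorbidity: np.ndarray | None = None
                        ) -> CensoringModel:
    """Fit pooled logistic models of monthly per-protocol censoring.

    ``pm`` must be a per-protocol person-month table carrying the
    ``pp_censored`` indicator and a ``row`` back-reference into ``cohort``.
    The numerator (stabilisation) model contains arm and time only; the
    denominator adds baseline covariates and, per spec, the monthly
    cumulative comorbidity count.
    """
    spec = spec or CensorModelSpec()
    c = _censor_indicator(pm, spec.include_admin_censoring)
    arms, Xn, num_names, Xd, den_names = _num_den_design(
        pm, cohort, covariates, spec, comorbidity)
    silent = tuple(a for a in arms
                   if c[(pm["arm"] == a).to_numpy()].sum() == 0)
    if silent:
        warnings.warn(f"no per-protocol censoring events in arm(s) {silent}; "
                      "their censor weights are 1")
    if c.sum() == 0:
        return CensoringModel(spec, None, None, num_names, den_names, arms,
                              silent_arms=silent, covariates=tuple(covariates))
    num_fit = fit_weighted_logistic(Xn, c, columns=num_names)
    den_fit = fit_weighted_logistic(Xd, c, columns=den_names, compress=False)
    return CensoringModel(spec, num_fit, den_fit, num_names, den_names, arms,
                          silent_arms=silent, covariates=tuple(covariates),
                          design_X=Xd)


def ipcw(pm: pd.DataFrame, model: CensoringModel, cohort: pd.DataFrame,
         comorbidity: np.ndarray | None = None) -> np.ndarray:
    """Time-varying stabilised censor weights, one per person-month row.

    Cumulative product of monthly uncensored-probability ratios, lagged one
    month (weights are 1 in month 1 before any censoring opportunity), then
    winsorised at the spec's percentile.
    """
    n = len(pm)
    if model.num_fit is None:
        return np.ones(n)
    arms, Xn, _, Xd, _ = _num_den_design(pm, cohort, model.covariates,
                                         model.spec, comorbidity)
    pc_num = model.num_fit.predict(Xn)
    pc_den = model.den_fit.predict(Xd)
    surv_ratio = (1.0 - pc_num) / np.clip(1.0 - pc_den, 1e-12, None)
    if (1.0 - pc_den < 1e-12).any():
        raise FloatingPointError(
            "censoring survival underflow: consider trimming or a simpler "
            "denominator model")
    if not model.spec.stabilised:
        surv_ratio = 1.0 / np.clip(1.0 - pc_den, 1e-12, None)

    # lagged cumulative product within each patient's consecutive months
    logr = np.log(surv_ratio)
    t = pm["t"].to_numpy()
    starts = np.flatnonzero(t == 1)
    cs = np.cumsum(logr)
    block_id = np.cumsum(t == 1) - 1
    offset_per_block = cs[starts] - logr[starts]
    lagged = np.exp(np.concatenate([[0.0], cs[:-1]])
                    - offset_per_block[block_id])
    w = np.where(t == 1, 1.0, lagged)
    cap = np.percentile(w, model.spec.trim_percentile)
    return np.minimum(w, cap)
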