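"""Discrete-time outcome models and effect measures.

The hazard model is a weighted pooled logistic regression on person-month
data:

    logit h(t, arm) = alpha + g(t) + sum_k beta_k arm_k [+ sum_k gamma_k arm_k * t]

with g(t) linear in month by default (a restricted cubic spline is
available).  Confounding is carried entirely by the analysis weights, so
the model contains only arm, time, and their product, and the predicted
cumulative incidence R(t) = 1 - prod_u (1 - h(u, arm)) is marginal in the
weighted population.  Risk differences and ratios compare R(t) between the
index arm and a comparator; hazard ratios come from the no-interaction
pooled logistic (rare-event approximation) or a continuous-time Cox model
with robust standard errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import HORIZON_MONTHS, MONTH_DAYS
from .glm import LogisticFit, fit_weighted_logistic

__all__ = [
    "followup_arrays",
    "expand_person_months",
    "HazardModel",
    "fit_pooled_logistic",
    "fit_hazard_from_followup",
    "predict_risk_curve",
    "contrast",
    "approximate_hr",
    "fit_cox",
    "wald_interaction_test",
]


def followup_arrays(cohort: pd.DataFrame, estimand: str = "itt",
                    outcome: str = "mace") -> tuple[np.ndarray, np.ndarray]:
    """Terminal month T_i and event indicator for the chosen estimand and
    outcome.  Per-protocol truncates at the per-protocol censor month (the
    event-first convention is already resolved upstream)."""
    if outcome == "mace":
        ev_m = cohort["itt_event_month"].to_numpy(float)
        cn_m = cohort["itt_censor_month"].to_numpy(float)
    else:
        ev_m = cohort[f"{outcome}_event_month"].to_numpy(float)
        cn_m = cohort[f"{outcome}_censor_month"].to_numpy(float)
    T = np.where(np.isnan(ev_m), cn_m, ev_m).astype(int)
    event = ~np.isnan(ev_m)
    if estimand == "pp":
        if outcome != "mace":
            raise ValueError("per-protocol follow-up is defined for the "
                             "composite outcome only")
        pp = cohort["pp_censor_month"].to_numpy(float)
        censored = ~np.isnan(pp)
        T = np.where(censored, np.fmin(pp, T), T).astype(int)
        event = event & ~censored
    elif estimand != "itt":
        raise ValueError("estimand must be 'itt' or 'pp'")
    return T, event


def expand_person_months(cohort: pd.DataFrame, estimand: str = "itt",
                         outcome: str = "mace",
                         weights: np.ndarray | None = None) -> pd.DataFrame:
    """Expand one row per patient into one row per person-month.

    A patient with terminal month T contributes months 1..T; the event
    indicator is 1 only in month T and only when follow-up ends in the
    chosen outcome.  Per-protocol rows additionally carry the artificial
    censoring indicator and its reason (input to the censoring model).
    """
    T, event = followup_arrays(cohort, estimand, outcome)
    n = len(cohort)
    idx = np.repeat(np.arange(n), T)
    month = np.arange(T.sum()) - np.repeat(np.cumsum(T) - T, T) + 1
    last = month == np.repeat(T, T)
    pm = pd.DataFrame({
        "patient_id": cohort["patient_id"].to_numpy()[idx],
        "t": month,
        "arm": cohort["arm"].to_numpy()[idx],
        "event": (last & np.repeat(event, T)).astype(int),
    })
    if weights is not None:
        pm["weight"] = np.asarray(weights, float)[idx]
    if estimand == "pp":
        pp = cohort["pp_censor_month"].notna().to_numpy()
        reason = cohort["pp_censor_reason"].to_numpy(object)
        pm["pp_censored"] = (last & np.repeat(pp, T)).astype(int)
        pm["pp_censor_reason"] = np.where(pm["pp_censored"].to_numpy(dtype=bool),
                                          reason[idx], None)
        pm["row"] = idx   # back-reference to the cohort row for covariates
    return pm


def _time_basis(t: np.ndarray, time_spec: str, knots) -> np.ndarray:
    t = np.asarray(t, float)
    if time_spec == "linear":
        return t[:, None]
    if time_spec != "spline":
        raise ValueError("time_spec must be 'linear' or 'spline'")
    k = np.asarray(knots, float)
    K = len(k)
    norm = (k[-1] - k[0]) ** 2

    def cub(x):
        return np.clip(x, 0, None) ** 3

    cols = [t]
    for j in range(K - 2):
        cols.append((cub(t - k[j])
                     - cub(t - k[-2]) * (k[-1] - k[j]) / (k[-1] - k[-2])
                     + cub(t - k[-1]) * (k[-2] - k[j]) / (k[-1] - k[-2]))
                    / norm)
    return np.column_stack(cols)


@dataclass
class HazardModel:
    """Fitted discrete-time hazard model over arms and months."""

    arms: tuple[str, ...]
    columns: list[str]
    coef: np.ndarray
    time_spec: str = "linear"
    knots: tuple[float, ...] = (6, 18, 30, 42, 54)
    include_time_interaction: bool = True
    unstable_arms: tuple[str, ...] = ()
    fit: LogisticFit = field(repr=False, default=None)

    def design(self, arm: str, t: np.ndarray) -> np.ndarray:
        if arm not in self.arms:
            raise ValueError(f"unknown arm {arm!r}")
        t = np.asarray(t, float)
        tb = _time_basis(t, self.time_spec, self.knots)
        cols = [np.ones(len(t)), tb]
        for a in self.arms[1:]:
            cols.append(np.full((len(t), 1), float(a == arm)))
        if self.include_time_interaction:
            for a in self.arms[1:]:
                cols.append((t * float(a == arm))[:, None])
        return np.column_stack(cols)

    def predict_hazard(self, arm: str, t: np.ndarray) -> np.ndarray:
        from scipy.special import expit
        return expit(self.design(arm, t) @ self.coef)


def _hazard_design(t, arm, arms, time_spec, knots, interaction):
    tb = _time_basis(t, time_spec, knots)
    names = ["_intercept"] + [f"t{j}" if j else "t" for j in range(tb.shape[1])]
    cols = [np.ones(len(t)), tb]
    arm = np.asarray(arm)
    for a in arms[1:]:
        cols.append((arm == a).astype(float)[:, None])
        names.append(f"arm={a}")
    if interaction:
        for a in arms[1:]:
            cols.append(((arm == a) * np.asarray(t, float))[:, None])
            names.append(f"arm={a}:t")
    return np.column_stack(cols), names


def fit_pooled_logistic(pm: pd.DataFrame, include_time_interaction: bool = True,
                        time_spec: str = "linear",
                        knots=(6, 18, 30, 42, 54),
                        weight_col: str | None = "weight",
                        arms: tuple[str, ...] | None = None) -> HazardModel:
    """Weighted pooled logistic regression on a person-month table."""
    arms = tuple(arms) if arms is not None else tuple(
        sorted(pd.unique(pm["arm"])))
    if pm["event"].sum() == 0:
        raise ValueError("no events: hazard model is not identifiable")
    w = (pm[weight_col].to_numpy(float)
         if weight_col and weight_col in pm.columns else None)
    X, names = _hazard_design(pm["t"].to_numpy(), pm["arm"].to_numpy(), arms,
                              time_spec, knots, include_time_interaction)
    fit = fit_weighted_logistic(X, pm["event"].to_numpy(float), w,
                                columns=names)
    ev_by_arm = pm.groupby("arm", observed=True)["event"].sum()
    unstable = tuple(a for a in arms if ev_by_arm.get(a, 0) == 0)
    return HazardModel(arms=arms, columns=names, coef=fit.coef,
                       time_spec=time_spec, knots=tuple(knots),
                       include_time_interaction=include_time_interaction,
                       unstable_arms=unstable, fit=fit)


def fit_hazard_from_followup(T: np.ndarray, event: np.ndarray,
                             arm: np.ndarray, weights: np.ndarray | None,
                             arms: tuple[str, ...],
                             include_time_interaction: bool = True,
                             time_spec: str = "linear",
                             knots=(6, 18, 30, 42, 54)) -> HazardModel:
    """Pooled logistic fit from per-patient follow-up without materialising
    person-month rows.

    Aggregates weighted events and at-risk totals per (arm, month) — an
    exact collapse of the person-month likelihood when weights are constant
    within patient — then fits grouped binomial rows.  This is the fast path
    the bootstrap uses.
    """
    T = np.asarray(T, int)
    event = np.asarray(event, bool)
    w = np.ones(len(T)) if weights is None else np.asarray(weights, float)
    arm = np.asarray(arm)
    horizon = HORIZON_MONTHS
    rows_t, rows_arm, rows_e, rows_n = [], [], [], []
    for a in arms:
        m = arm == a
        wT = np.bincount(T[m], weights=w[m], minlength=horizon + 1)
        wE = np.bincount(T[m & event], weights=w[m & event],
                         minlength=horizon + 1)
        atrisk = np.cumsum(wT[::-1])[::-1][1:]      # sum_{T >= t}, t = 1..60
        ev = wE[1:]
        keep = atrisk > 0
        rows_t.append(np.arange(1, horizon + 1)[keep])
        rows_arm.append(np.full(keep.sum(), a, object))
        rows_e.append(ev[keep])
        rows_n.append(atrisk[keep])
    t = np.concatenate(rows_t)
    a_col = np.concatenate(rows_arm)
    e = np.concatenate(rows_e)
    nn = np.concatenate(rows_n)
    if e.sum() == 0:
        raise ValueError("no events: hazard model is not identifiable")
    X, names = _hazard_design(t, a_col, arms, time_spec, knots,
                              include_time_interaction)
    fit = fit_weighted_logistic(X, e / nn, nn, columns=names, compress=False)
    unstable = tuple(a for a in arms
                     if e[np.asarray(a_col) == a].sum() == 0)
    return HazardModel(arms=arms, columns=names, coef=fit.coef,
                       time_spec=time_spec, knots=tuple(knots),
                       include_time_interaction=include_time_interaction,
                       unstable_arms=unstable, fit=fit)


def predict_risk_curve(model: HazardModel, arm: str,
                       horizon: int = HORIZON_MONTHS) -> np.ndarray:
    """Cumulative incidence R(t), t = 0..horizon, from the fitted hazards:
    R(t) = 1 - prod_{u<=t} (1 - h(u, arm))."""
    if horizon > HORIZON_MONTHS:
        raise ValueError("horizon beyond the 60-month follow-up")
    h = model.predict_hazard(arm, np.arange(1, horizon + 1))
    R = np.concatenate([[0.0], 1.0 - np.cumprod(1.0 - h)])
    assert (np.diff(R) >= -1e-15).all() and (R >= 0).all() and (R <= 1).all(), \
        "risk curve must be non-decreasing within [0, 1]"
    return R


def contrast(curve_index: np.ndarray, curve_comp: np.ndarray,
             horizon: int) -> dict[str, float]:
    """Risk difference (per 1000) and risk ratio at a horizon, index arm
    minus/over comparator."""
    r_a, r_c = float(curve_index[horizon]), float(curve_comp[horizon])
    out = {"risk_index": r_a, "risk_comp": r_c,
           "rd_per_1000": 1000.0 * (r_a - r_c)}
    out["rr"] = r_a / r_c if r_c > 0 else np.nan
    return out


def approximate_hr(model: HazardModel) -> dict[str, float]:
    """Hazard ratios of the index arm versus each comparator from the
    no-interaction pooled logistic (exp of minus the comparator's log-odds
    coefficient; a valid HR approximation when monthly hazards are small)."""
    if model.include_time_interaction:
        raise ValueError("approximate HRs require the no-interaction model")
    coefs = dict(zip(model.columns, model.coef))
    return {a: float(np.exp(-coefs[f"arm={a}"])) for a in model.arms[1:]}


@dataclass
class CoxResult:
    arms: tuple[str, ...]
    params: pd.Series
    cov: pd.DataFrame
    hr: dict[str, float]          # index arm vs each comparator
    fitter: object = field(repr=False, default=None)


def _cox_frame(cohort, estimand, outcome, arms):
    T, event = followup_arrays(cohort, estimand, outcome)
    df = pd.DataFrame({
        "duration": (T - 0.5) * MONTH_DAYS,
        "event": event.astype(int)})
    for a in arms[1:]:
        df[f"arm={a}"] = (cohort["arm"] == a).to_numpy(float)
    return df


def fit_cox(cohort: pd.DataFrame, weights: np.ndarray | None = None,
            covariate_adjusted: bool = False, covariates=(),
            estimand: str = "itt", outcome: str = "mace",
            arms: tuple[str, ...] | None = None) -> CoxResult:
    """Continuous-time Cox model with robust (sandwich) standard errors.

    Either weighted (weights carry the confounding adjustment) or
    covariate-adjusted (baseline covariates enter the linear predictor
    instead of weights).  Event times sit at mid-month on the day scale,
    matching the discrete-time convention.
    """
    from lifelines import CoxPHFitter
    arms = tuple(arms) if arms is not None else tuple(
        sorted(pd.unique(cohort["arm"])))
    df = _cox_frame(cohort, estimand, outcome, arms)
    if df["event"].sum() == 0:
        raise ValueError("no events: Cox model is not identifiable")
    if covariate_adjusted:
        from .weights import build_design
        X, names = build_design(cohort, covariates, add_intercept=False)
        for j, nm in enumerate(names):
            df[nm] = X[:, j]
    kw = {}
    if weights is not None and not covariate_adjusted:
        df["_w"] = np.asarray(weights, float)
        kw["weights_col"] = "_w"
    cph = CoxPHFitter()
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")   # non-integer weights are intended
        cph.fit(df, duration_col="duration", event_col="event",
                robust=True, **kw)
    hr = {a: float(np.exp(-cph.params_[f"arm={a}"])) for a in arms[1:]}
    return CoxResult(arms=arms, params=cph.params_,
                     cov=cph.variance_matrix_, hr=hr, fitter=cph)


def wald_interaction_test(cohort: pd.DataFrame, weights: np.ndarray,
                          modifier: str, estimand: str = "itt",
                          outcome: str = "mace",
                          arms: tuple[str, ...] | None = None) -> float:
    """Robust Wald test of arm x modifier interaction in the weighted Cox
    model: chi-square on the interaction coefficient block.

    Age and starting dose enter as continuous (standardised); sex as a male
    indicator; ethnicity as non-White vs White; SMI diagnosis as two
    dummies.  Returns the two-sided p-value.
    """
    from lifelines import CoxPHFitter
    arms = tuple(arms) if arms is not None else tuple(
        sorted(pd.unique(cohort["arm"])))
    s = cohort[modifier]
    if s.isna().any():
        raise ValueError("modifier must be complete (run per imputed dataset)")
    if modifier in ("age", "starting_dose_olz_equiv", "bmi"):
        x = s.to_numpy(float)
        mod_cols = {modifier: (x - x.mean()) / x.std()}
    elif modifier == "sex":
        mod_cols = {"sex=M": (s == "M").to_numpy(float)}
    elif modifier == "ethnicity":
        mod_cols = {"ethnicity=nonwhite": (s != "White").to_numpy(float)}
    else:
        levels = sorted(pd.unique(s), key=str)
        mod_cols = {f"{modifier}={lev}": (s == lev).to_numpy(float)
                    for lev in levels[1:]}
    for v in mod_cols.values():
        if np.std(v) == 0:
            raise ValueError(f"modifier {modifier!r} is constant: "
                             "interaction test undefined")

    df = _cox_frame(cohort, estimand, outcome, arms)
    inter_names = []
    for nm, x in mod_cols.items():
        df[nm] = x
        for a in arms[1:]:
            cn = f"arm={a}:{nm}"
            df[cn] = df[f"arm={a}"] * x
            inter_names.append(cn)
    df["_w"] = np.asarray(weights, float)
    cph = CoxPHFitter()
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col="duration", event_col="event",
                weights_col="_w", robust=True)
    b = cph.params_[inter_names].to_numpy()
    V = cph.variance_matrix_.loc[inter_names, inter_names].to_numpy()
    stat = float(b @ np.linalg.solve(V, b))
    return float(stats.chi2.sf(stat, df=len(b)))
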