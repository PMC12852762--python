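"""Multiple imputation by chained equations over baseline covariates.

A deliberately small, auditable MICE: continuous covariates are imputed by
predictive mean matching (type-1 PMM — Bayesian coefficient draw, then a
uniform draw among the k observed cases with closest predicted means) and
categorical covariates by a multinomial-logistic draw from the fitted
class probabilities.  The treatment arm, the event indicator and log
follow-up time always enter the predictor matrix (survival-aware
imputation); each of the m completed datasets runs on an independent
substream of the seed.  PMM guarantees imputations lie in the observed
support of each variable.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .config import ImputationConfig
from .glm import fit_softmax
from .weights import _column_kind, build_design

__all__ = ["mice_impute", "complete_case"]


def _extras(cohort: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Always-observed analysis variables added to every predictor matrix:
    arm dummies, event indicator, log follow-up time."""
    arms = sorted(pd.unique(cohort["arm"]))
    cols, names = [], []
    for a in arms[1:]:
        cols.append((cohort["arm"] == a).to_numpy(float))
        names.append(f"arm={a}")
    ev = cohort["itt_event_month"].notna().to_numpy(float)
    T = (cohort["itt_event_month"].fillna(0).to_numpy(float)
         + cohort["itt_censor_month"].fillna(0).to_numpy(float))
    cols += [ev, np.log(np.clip(T, 1, None))]
    names += ["event", "log_t"]
    return np.column_stack(cols), names


def _pmm_draw(y_obs, yhat_obs, yhat_mis, k, rng):
    """Predictive mean matching: for each missing case, one of the k
    observed donors with closest predicted mean, drawn uniformly."""
    order = np.argsort(yhat_obs, kind="stable")
    sy, sv = yhat_obs[order], y_obs[order]
    n_obs = len(sy)
    k = min(k, n_obs)
    pos = np.searchsorted(sy, yhat_mis)
    # candidate window of 2k donors around the insertion point
    lo = np.clip(pos - k, 0, max(n_obs - 2 * k, 0))
    offs = np.arange(2 * k)
    cand = np.clip(lo[:, None] + offs[None, :], 0, n_obs - 1)
    dist = np.abs(sy[cand] - yhat_mis[:, None])
    nearest = np.argsort(dist, axis=1, kind="stable")[:, :k]
    pick = nearest[np.arange(len(yhat_mis)), rng.integers(0, k, len(yhat_mis))]
    return sv[cand[np.arange(len(yhat_mis)), pick]]


def _impute_once(cohort, targets, kinds, config, rng):
    df = cohort.copy()
    masks = {v: df[v].isna().to_numpy() for v in targets}
    # initial fill: random draws from the observed values
    for v in targets:
        obs = df.loc[~masks[v], v].to_numpy()
        df.loc[masks[v], v] = rng.choice(obs, size=masks[v].sum())
    Xe, _ = _extras(cohort)
    trace = []
    for it in range(config.n_iterations):
        for v in targets:
            m = masks[v]
            if config.predictor_matrix is not None:
                preds = list(config.predictor_matrix[v])
            else:
                preds = [c for c in _default_predictors(df, targets) if c != v]
            Xb, _ = build_design(df, preds)
            X = np.column_stack([Xb, Xe])
            if kinds[v] == "continuous":
                y = df[v].to_numpy(float)
                Xo, yo = X[~m], y[~m]
                XtX = Xo.T @ Xo + 1e-8 * np.eye(X.shape[1])
                beta = np.linalg.solve(XtX, Xo.T @ yo)
                resid = yo - Xo @ beta
                dof = max(len(yo) - X.shape[1], 1)
                sigma2 = (resid @ resid) / rng.chisquare(dof)
                cov = sigma2 * np.linalg.inv(XtX)
                beta_star = rng.multivariate_normal(beta, cov,
                                                    method="cholesky")
                df.loc[m, v] = _pmm_draw(yo, Xo @ beta, X[m] @ beta_star,
                                         config.pmm_donors, rng)
            else:
                levels = sorted(pd.unique(df.loc[~m, v]), key=str)
                y_idx = pd.Categorical(df.loc[~m, v],
                                       categories=levels).codes
                fit = fit_softmax(X[~m], y_idx, len(levels))
                P = fit.predict_proba(X[m])
                u = rng.random(len(P))
                draw = (u[:, None] >= np.cumsum(P, axis=1)).sum(axis=1)
                df.loc[m, v] = np.asarray(levels, object)[draw]
        trace.append({v: float(pd.to_numeric(df[v], errors="coerce").mean())
                      if kinds[v] == "continuous" else
                      float((df[v] == df[v].mode()[0]).mean())
                      for v in targets})
    # restore dtypes
    for v in targets:
        if kinds[v] == "continuous":
            df[v] = df[v].astype(float)
    return df, trace


def _default_predictors(df, targets):
    candidates = ["age", "sex", "ethnicity", "smi_diagnosis", "imd_quintile",
                  "diabetes", "hypertension", "smoking", "bmi",
                  "prior_antipsychotic", "starting_dose_olz_equiv"]
    return [c for c in candidates if c in df.columns]


def mice_impute(cohort: pd.DataFrame,
                config: ImputationConfig | None = None) -> list[pd.DataFrame]:
    """Chained-equations imputation: m completed copies of the cohort.

    Raises if any variable to impute has zero observed values; returns m
    identical copies when nothing is missing.  Per-iteration chain means
    are logged on each completed frame as ``df.attrs['mice_trace']``.
    """
    config = config or ImputationConfig()
    covs = _default_predictors(cohort, ())
    targets = [v for v in covs if cohort[v].isna().any()]
    for v in targets:
        if cohort[v].notna().sum() == 0:
            raise ValueError(f"variable {v!r} has no observed values")
    if cohort["arm"].isna().any():
        raise ValueError("treatment must be fully observed")
    if not targets:
        return [cohort.copy() for _ in range(config.m)]
    kinds = {v: _column_kind(cohort[v], v) for v in targets}
    kinds = {v: ("continuous" if k == "continuous" else "categorical")
             for v, k in kinds.items()}
    streams = np.random.SeedSequence(config.seed).spawn(config.m)
    out = []
    for ch in streams:
        rng = np.random.Generator(np.random.PCG64(ch))
        df, trace = _impute_once(cohort, targets, kinds, config, rng)
        df.attrs["mice_trace"] = trace
        out.append(df)
    return out


def complete_case(cohort: pd.DataFrame,
                  covariates=None) -> tuple[pd.DataFrame, int]:
    """Drop rows with any missing modelled covariate.

    Returns (retained rows, number removed); warns when nothing survives.
    """
    covs = covariates if covariates is not None else \
        _default_predictors(cohort, ())
    covs = [c for c in covs if c in cohort.columns]
    keep = ~cohort[covs].isna().any(axis=1)
    removed = int((~keep).sum())
    if keep.sum() == 0:
        warnings.warn("complete-case analysis removed every row")
    return cohort[keep].reset_index(drop=True), removed
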