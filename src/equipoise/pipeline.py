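"""End-to-end emulation pipeline.

Composes the stages — synthetic tables (or supplied raw tables) → cohort
construction → missing-data handling → propensity weighting with balance
checks → discrete-time outcome models → stratified bootstrap + Rubin
pooling + BCa intervals — for the intention-to-treat primary analysis, the
per-protocol analysis with optional censor weighting, and the sensitivity
grid.  Every stage derives its randomness from the plan's master seed, so a
run is byte-identical given (inputs, plan).
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .censor_weights import (cumulative_comorbidity_counts,
                             fit_censoring_model, ipcw)
from .cohort import build_cohort
from .config import (ARMS, AnalysisPlan, BootstrapPlan, CensorModelSpec,
                     EligibilityCriteria, ImputationConfig, SimulationConfig)
from .impute import complete_case, mice_impute
from .inference import bca_interval, bootstrap_pipeline, rubin_pool
from .outcome_models import (approximate_hr, contrast, expand_person_months,
                             fit_cox, fit_hazard_from_followup,
                             fit_pooled_logistic, followup_arrays,
                             predict_risk_curve, wald_interaction_test)
from .simulate import RawTables, apply_missingness, generate_cohort
from .weights import (effective_sample_size, fit_propensity, iptw_weights,
                      overlap_weights, standardized_differences)

__all__ = ["BalanceError", "run_emulation", "sensitivity_suite",
           "prepare_cohort", "prepare_datasets"]


class BalanceError(RuntimeError):
    """Raised when post-weighting imbalance exceeds the threshold; carries
    the offending balance table (the planned doubly robust fallback is not
    implemented)."""

    def __init__(self, message, balance: pd.DataFrame):
        super().__init__(message)
        self.balance = balance


def _sub_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2 ** 31))


def prepare_cohort(source: SimulationConfig | RawTables,
                   plan: AnalysisPlan) -> tuple[pd.DataFrame, dict]:
    """Raw tables (generated if a config is supplied) → analysis cohort."""
    if isinstance(source, SimulationConfig):
        tables = apply_missingness(generate_cohort(source), source)
    else:
        tables = source
    criteria = EligibilityCriteria(inclusive_smi=plan.eligibility == "inclusive")
    cohort, tally = build_cohort(tables, criteria)
    cohort["_row0"] = np.arange(len(cohort))
    return cohort, {"flow": tally, "tables": tables}


def prepare_datasets(cohort: pd.DataFrame, plan: AnalysisPlan,
                     seed: int) -> list[pd.DataFrame]:
    """Missing-data handling: m imputed copies, a complete-case cohort, or
    the cohort itself when nothing is missing."""
    covs = [c for c in plan.covariates if c in cohort.columns]
    any_missing = cohort[covs].isna().any().any()
    if plan.missing == "complete_case":
        cc, _ = complete_case(cohort, covs)
        return [cc]
    if not any_missing:
        return [cohort]
    cfg = ImputationConfig(m=plan.m_imputations, seed=seed)
    return mice_impute(cohort, cfg)


def _estimate(df: pd.DataFrame, plan: AnalysisPlan,
              comorbidity: np.ndarray | None = None,
              want_cox: bool = False) -> dict:
    """One full run of the estimation procedure on one (possibly
    resampled) completed dataset: propensity → weights → (IPCW) → pooled
    logistic → risks, contrasts, HRs."""
    arms = ARMS
    model = fit_propensity(df, plan.covariates, arms=arms)
    ws = (overlap_weights(model, df["arm"]) if plan.weighting == "overlap"
          else iptw_weights(model, df["arm"]))
    out: dict[str, float] = {}

    if plan.estimand == "pp" and plan.censor_weighting != "none":
        spec = CensorModelSpec(covariate_set=(
            "baseline_plus_timevarying"
            if plan.censor_weighting == "baseline_plus_timevarying"
            else "baseline_only"))
        pm = expand_person_months(df, "pp", plan.outcome, weights=ws.weights)
        com = None
        if spec.covariate_set == "baseline_plus_timevarying":
            com = comorbidity[df["_row0"].to_numpy()]
        cmod = fit_censoring_model(pm, df, plan.covariates, spec, com)
        cw = ipcw(pm, cmod, df, com)
        pm["weight"] = pm["weight"].to_numpy() * cw
        hm = fit_pooled_logistic(pm, include_time_interaction=True, arms=arms)
        hm0 = fit_pooled_logistic(pm, include_time_interaction=False,
                                  arms=arms)
    else:
        T, event = followup_arrays(df, plan.estimand, plan.outcome)
        arm = df["arm"].to_numpy()
        hm = fit_hazard_from_followup(T, event, arm, ws.weights, arms,
                                      include_time_interaction=True)
        hm0 = fit_hazard_from_followup(T, event, arm, ws.weights, arms,
                                       include_time_interaction=False)

    curves = {a: predict_risk_curve(hm, a) for a in arms}
    for h in plan.horizons:
        out[f"risk_{h}m_{arms[0]}"] = float(curves[arms[0]][h])
        for a in arms[1:]:
            c = contrast(curves[arms[0]], curves[a], h)
            out[f"risk_{h}m_{a}"] = c["risk_comp"]
            out[f"rd_per_1000_{h}m_{a}"] = c["rd_per_1000"]
            out[f"rr_{h}m_{a}"] = c["rr"]
    for a, v in approximate_hr(hm0).items():
        out[f"hr_plr_{a}"] = v
    if want_cox:
        cox = fit_cox(df, ws.weights, estimand=plan.estimand,
                      outcome=plan.outcome, arms=arms)
        for a, v in cox.hr.items():
            out[f"hr_cox_{a}"] = v
    out["_curves"] = curves
    out["_weights"] = ws.weights
    return out


def run_emulation(source: SimulationConfig | RawTables,
                  plan: AnalysisPlan | None = None,
                  outdir: str | Path | None = None) -> dict:
    """Execute one analysis cell end to end and return a results bundle.

    The bundle holds Rubin-pooled point estimates with BCa bootstrap CIs
    per contrast and measure, per-arm risk curves, the balance table, the
    eligibility flow tally, effective sample sizes, and a run manifest.
    Aborts with :class:`BalanceError` if any mean post-weighting
    standardised difference exceeds the threshold.
    """
    plan = plan or AnalysisPlan()
    ss = np.random.SeedSequence(plan.seed).spawn(3)
    cohort, meta = prepare_cohort(source, plan)
    if cohort.empty:
        raise ValueError("empty cohort after eligibility")
    datasets = prepare_datasets(cohort, plan, _sub_seed(ss[0]))
    arms = ARMS

    comorbidity = None
    if plan.censor_weighting == "baseline_plus_timevarying":
        comorbidity = cumulative_comorbidity_counts(
            cohort, meta["tables"].episodes)

    # --- point estimates + balance per completed dataset ------------------
    per_imp: list[dict] = []
    balances, esss, curve_sets = [], [], []
    for df in datasets:
        est = _estimate(df, plan, comorbidity, want_cox=True)
        w = est.pop("_weights")
        curve_sets.append(est.pop("_curves"))
        per_imp.append(est)
        bal = pd.concat(
            [standardized_differences(df, w, (arms[0], a), plan.covariates)
             for a in arms[1:]], axis=1)
        balances.append(bal)
        esss.append(effective_sample_size(w, df["arm"]))
    balance = sum(balances) / len(balances)
    ess = sum(esss) / len(esss)
    if balance.abs().to_numpy().max() > plan.balance_threshold:
        raise BalanceError(
            f"mean standardised difference "
            f"{balance.abs().to_numpy().max():.3f} exceeds "
            f"{plan.balance_threshold} after weighting; causal contrast "
            "aborted (doubly robust fallback not implemented)", balance)

    measures = sorted(per_imp[0])
    points = {m: rubin_pool([e[m] for e in per_imp], measure=m)
              for m in measures}

    # --- bootstrap of the full procedure -----------------------------------
    bplan = BootstrapPlan(
        samples_per_imputation=plan.bootstrap.samples_per_imputation,
        seed=_sub_seed(ss[1]))

    def estimator(boot: pd.DataFrame) -> dict:
        est = _estimate(boot, plan, comorbidity, want_cox=False)
        est.pop("_curves")
        est.pop("_weights")
        return est

    draws = bootstrap_pipeline(datasets, bplan, estimator)
    results = {}
    for m in measures:
        if m.startswith("hr_cox"):
            continue
        blocks = np.asarray([e[m] for e in per_imp], float)
        res = bca_interval(draws[m].to_numpy(), points[m],
                           block_estimates=blocks,
                           log_scale=m.startswith(("rr", "hr")))
        results[m] = {"point": points[m], "ci": list(res.ci),
                      "n_draws": res.n_draws, "z0": res.z0,
                      "acceleration": res.acceleration,
                      "ci_method": "bca"}
    for m in measures:
        if m.startswith("hr_cox"):
            results[m] = {"point": points[m], "ci": None,
                          "ci_method": "none"}

    # --- risk curves (pooled across imputations) ----------------------------
    curve_rows = [{"arm": a, "t": t, "R": r}
                  for cs in curve_sets for a, R in cs.items()
                  for t, r in enumerate(R)]
    curves = (pd.DataFrame(curve_rows)
              .groupby(["arm", "t"], as_index=False)["R"].mean())

    # --- subgroup effect-modification tests ---------------------------------
    subgroup_p = {}
    for mod in plan.subgroups:
        ps = []
        for df in datasets:
            model = fit_propensity(df, plan.covariates, arms=arms)
            w = (overlap_weights(model, df["arm"]).weights
                 if plan.weighting == "overlap"
                 else iptw_weights(model, df["arm"]).weights)
            ps.append(wald_interaction_test(df, w, mod,
                                            estimand=plan.estimand))
        subgroup_p[mod] = float(np.median(ps))

    bundle = {
        "plan": _plan_manifest(plan),
        "n_cohort": int(len(cohort)),
        "n_imputations": len(datasets),
        "flow": meta["flow"],
        "ess_per_arm": {str(k): float(v) for k, v in ess.items()},
        "ess_total": float(ess.sum()),
        "max_mean_std_difference": float(balance.abs().to_numpy().max()),
        "results": results,
        "subgroup_wald_p": subgroup_p,
        "bootstrap_failures": int(draws.attrs.get("failures", 0)),
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "results.json").write_text(
            json.dumps(bundle, indent=2, sort_keys=True))
        balance.to_csv(outdir / "balance.csv")
        curves.to_csv(outdir / "risk_curves.csv", index=False)
        (outdir / "flow.json").write_text(
            json.dumps(meta["flow"], indent=2))
    bundle["balance"] = balance
    bundle["risk_curves"] = curves
    return bundle


def _plan_manifest(plan: AnalysisPlan) -> dict:
    d = asdict(plan)
    d["bootstrap"] = asdict(plan.bootstrap)
    return d


#: the sensitivity grid: name -> plan overrides
SENSITIVITY_GRID = {
    "primary_overlap_plr": {},
    "iptw_plr": {"weighting": "iptw"},
    "complete_case": {"missing": "complete_case"},
    "inclusive_eligibility": {"eligibility": "inclusive"},
}

PP_GRID = {
    "pp_overlap": {"estimand": "pp"},
    "pp_ipcw_baseline": {"estimand": "pp", "censor_weighting": "baseline"},
    "pp_ipcw_timevarying": {"estimand": "pp",
                            "censor_weighting": "baseline_plus_timevarying"},
    "pp_iptw": {"estimand": "pp", "weighting": "iptw"},
}


def sensitivity_suite(source: SimulationConfig | RawTables,
                      base_plan: AnalysisPlan | None = None,
                      include_pp: bool = True,
                      outdir: str | Path | None = None) -> pd.DataFrame:
    """Run the sensitivity grid around a primary ITT plan and return a
    forest-plot-ready table (one row per analysis x contrast x measure).

    Per-cell failures are isolated: a failing cell contributes NaN rows and
    the grid completes.  Cox-based cells (weighted and covariate-adjusted
    Cox) are included as point estimates from the pooled datasets.
    """
    base_plan = base_plan or AnalysisPlan()
    if base_plan.estimand != "itt":
        raise ValueError("the sensitivity grid is built around the primary "
                         "intention-to-treat plan")
    grid = dict(SENSITIVITY_GRID)
    if include_pp:
        grid.update(PP_GRID)
    rows = []
    for name, overrides in grid.items():
        plan = AnalysisPlan(**{**_plan_manifest(base_plan), **overrides,
                               "bootstrap": base_plan.bootstrap})
        try:
            bundle = run_emulation(source, plan)
            for m, r in bundle["results"].items():
                rows.append({"analysis": name, "measure": m,
                             "point": r["point"],
                             "ci_lo": r["ci"][0] if r["ci"] else np.nan,
                             "ci_hi": r["ci"][1] if r["ci"] else np.nan})
        except Exception as exc:          # isolate per-cell failures
            rows.append({"analysis": name, "measure": "error",
                         "point": np.nan, "ci_lo": np.nan, "ci_hi": np.nan,
                         "note": str(exc)})
    # covariate-adjusted Cox on the primary datasets (no weighting)
    try:
        cohort, _ = prepare_cohort(source, base_plan)
        datasets = prepare_datasets(
            cohort, base_plan,
            _sub_seed(np.random.SeedSequence(base_plan.seed).spawn(3)[0]))
        hrs = []
        for df in datasets:
            cox = fit_cox(df, covariate_adjusted=True,
                          covariates=base_plan.covariates, arms=ARMS)
            hrs.append(cox.hr)
        for a in ARMS[1:]:
            rows.append({"analysis": "adjusted_cox",
                         "measure": f"hr_cox_{a}",
                         "point": rubin_pool([h[a] for h in hrs],
                                             log_scale=True),
                         "ci_lo": np.nan, "ci_hi": np.nan})
    except Exception as exc:
        rows.append({"analysis": "adjusted_cox", "measure": "error",
                     "point": np.nan, "ci_lo": np.nan, "ci_hi": np.nan,
                     "note": str(exc)})
    out = pd.DataFrame(rows)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        out.to_csv(outdir / "sensitivity_grid.csv", index=False)
    return out
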