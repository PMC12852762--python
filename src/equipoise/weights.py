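"""Multinomial propensity estimation, generalised overlap weights, IPTW
sensitivity weights, and covariate-balance diagnostics.

The overlap weight of patient i in arm Z_i is

    w_i = (1 / p_{i,Z_i}) / sum_k (1 / p_{ik}),

the inverse probability of the received treatment normalised by the sum of
inverse probabilities across all arms.  It targets the population at
clinical equipoise, is bounded by construction (no trimming needed), and
for two arms reduces to the opposite arm's propensity.  IPTW uses
stabilised weights Pr(arm) / p_{i,Z_i}, winsorised at a percentile cap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .glm import SeparationError, SoftmaxFit, fit_softmax

__all__ = [
    "build_design",
    "PropensityModel",
    "WeightSet",
    "fit_propensity",
    "overlap_weights",
    "iptw_weights",
    "standardized_differences",
    "effective_sample_size",
    "improve_design",
]

#: covariates modelled as categorical in the analysis design
CATEGORICAL = {"sex", "ethnicity", "smi_diagnosis", "smoking", "imd_quintile"}


def _column_kind(s: pd.Series, name: str) -> str:
    if name in CATEGORICAL or s.dtype == object:
        return "categorical"
    vals = pd.unique(s.dropna())
    if len(vals) <= 2 and set(np.asarray(vals)) <= {0, 1}:
        return "binary"
    return "continuous"


def build_design(df: pd.DataFrame, covariates, extra_terms=(),
                 add_intercept: bool = True):
    """Analysis-side design matrix: one-hot categoricals (first level as
    reference, levels sorted), 0/1 binaries, continuous standardised by the
    sample mean/SD.  ``extra_terms`` adds candidate nonlinear terms of the
    form ``'x^2'`` or ``'a:b'`` built from already-present columns.

    Returns (X, column names).  Raises on missing cells: weighting runs on
    completed (imputed) data only.
    """
    cols: list[np.ndarray] = []
    names: list[str] = []
    if add_intercept:
        cols.append(np.ones(len(df)))
        names.append("_intercept")
    base: dict[str, np.ndarray] = {}
    for c in covariates:
        s = df[c]
        if s.isna().any():
            raise ValueError(f"covariate {c!r} has missing values; impute first")
        kind = _column_kind(s, c)
        if kind == "categorical":
            levels = sorted(pd.unique(s), key=str)
            for lev in levels[1:]:
                x = (s == lev).to_numpy(float)
                base[f"{c}={lev}"] = x
        elif kind == "binary":
            base[c] = s.to_numpy(float)
        else:
            x = s.to_numpy(float)
            sd = x.std()
            base[c] = (x - x.mean()) / (sd if sd > 0 else 1.0)
    for name, x in base.items():
        cols.append(x)
        names.append(name)
    for term in extra_terms:
        if "^2" in term:
            src = term[:term.index("^")]
            if src not in base:
                raise KeyError(f"unknown design column {src!r} in {term!r}")
            cols.append(base[src] ** 2)
        elif ":" in term:
            a, b = term.split(":")
            cols.append(base[a] * base[b])
        else:
            raise ValueError(f"cannot parse extra term {term!r}")
        names.append(term)
    X = np.column_stack(cols)
    # drop collinear columns (beyond the intercept); cheap full-rank check
    # on the Gram matrix first, per-column elimination only when needed
    G = X.T @ X
    try:
        np.linalg.cholesky(G + 1e-10 * np.trace(G) / len(G) * np.eye(len(G)))
        return X, names
    except np.linalg.LinAlgError:
        pass
    keep = [0] if add_intercept else []
    start = 1 if add_intercept else 0
    for j in range(start, X.shape[1]):
        sub = [*keep, j]
        if np.linalg.matrix_rank(G[np.ix_(sub, sub)]) == len(sub):
            keep.append(j)
        else:
            import warnings
            warnings.warn(f"dropping collinear design column {names[j]!r}")
    return X[:, keep], [names[j] for j in keep]


@dataclass
class PropensityModel:
    """Fitted multinomial propensity model.

    ``probs`` holds p_ik for every patient and arm (rows sum to one);
    ``coef`` is (n_arms-1, n_columns) with the first arm as reference.
    """

    arms: tuple[str, ...]
    columns: list[str]
    coef: np.ndarray
    probs: np.ndarray
    fit: SoftmaxFit = field(repr=False, default=None)

    def __post_init__(self):
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("propensities must sum to 1 per patient")


def fit_propensity(cohort: pd.DataFrame, covariates, extra_terms=(),
                   arm_col: str = "arm",
                   arms: tuple[str, ...] | None = None) -> PropensityModel:
    """Maximum-likelihood multinomial logistic fit of arm on covariates."""
    if cohort[arm_col].isna().any():
        raise ValueError("treatment must be fully observed")
    arms = tuple(arms) if arms is not None else tuple(
        sorted(pd.unique(cohort[arm_col])))
    X, names = build_design(cohort, covariates, extra_terms)
    y_idx = pd.Categorical(cohort[arm_col], categories=arms).codes
    if (y_idx < 0).any():
        raise ValueError("arm labels outside the declared arm set")
    try:
        fit = fit_softmax(X, y_idx, len(arms), classes=arms, columns=names)
    except SeparationError:
        raise
    probs = fit.predict_proba(X)
    return PropensityModel(arms=arms, columns=names, coef=fit.coef,
                           probs=probs, fit=fit)


@dataclass
class WeightSet:
    """Per-patient analysis weights with provenance."""

    weights: np.ndarray
    scheme: str                   # 'overlap' | 'iptw'
    stabilised: bool = False
    trim_percentile: float | None = None
    note: str = ""

    def __post_init__(self):
        w = np.asarray(self.weights, float)
        if not np.isfinite(w).all() or (w < 0).any():
            raise ValueError("weights must be finite and non-negative")
        self.weights = w


def overlap_weights(model: PropensityModel, arm_assignments) -> WeightSet:
    """Normalised generalised overlap weights (bounded; no trimming)."""
    p = model.probs
    if (p <= 0).any():
        raise ValueError("zero fitted propensity: refit or clip upstream")
    arm_idx = pd.Categorical(arm_assignments, categories=model.arms).codes
    inv = 1.0 / p
    own = inv[np.arange(len(p)), arm_idx]
    w = own / inv.sum(axis=1)
    return WeightSet(w, "overlap",
                     note="1/p_own normalised by sum_k 1/p_k")


def iptw_weights(model: PropensityModel, arm_assignments,
                 trim_percentile: float = 99.0) -> WeightSet:
    """Stabilised inverse-probability-of-treatment weights, winsorised at
    the given percentile (capping, not deletion)."""
    p = model.probs
    if (p <= 0).any():
        raise ValueError("zero fitted propensity: refit or clip upstream")
    arm_idx = pd.Categorical(arm_assignments, categories=model.arms).codes
    n = len(p)
    prev = np.bincount(arm_idx, minlength=len(model.arms)) / n
    w = prev[arm_idx] / p[np.arange(n), arm_idx]
    if trim_percentile is not None:
        cap = np.percentile(w, trim_percentile)
        w = np.minimum(w, cap)
    return WeightSet(w, "iptw", stabilised=True,
                     trim_percentile=trim_percentile,
                     note="Pr(arm)/p_own, capped at percentile")


def standardized_differences(cohort: pd.DataFrame, weights: np.ndarray,
                             arm_pair: tuple[str, str], covariates,
                             arm_col: str = "arm") -> pd.Series:
    """Weighted standardised differences d for one arm pair.

    Continuous: d = (weighted mean_1 - weighted mean_2) / sqrt((s1^2+s2^2)/2)
    with *unweighted* pooled SDs, so weighting moves the numerator only.
    Categorical covariates contribute one d per level on the same scale.
    """
    w = np.asarray(weights, float)
    m1 = (cohort[arm_col] == arm_pair[0]).to_numpy()
    m2 = (cohort[arm_col] == arm_pair[1]).to_numpy()
    if not m1.any() or not m2.any():
        raise ValueError(f"empty arm in pair {arm_pair}")
    out = {}

    def d_of(x):
        s1, s2 = x[m1].std(ddof=1), x[m2].std(ddof=1)
        denom = np.sqrt((s1 ** 2 + s2 ** 2) / 2)
        if denom == 0:
            return 0.0
        mu1 = np.average(x[m1], weights=w[m1])
        mu2 = np.average(x[m2], weights=w[m2])
        return (mu1 - mu2) / denom

    for c in covariates:
        s = cohort[c]
        if _column_kind(s, c) == "categorical":
            for lev in sorted(pd.unique(s.dropna()), key=str):
                out[f"{c}={lev}"] = d_of((s == lev).to_numpy(float))
        else:
            out[c] = d_of(s.to_numpy(float))
    return pd.Series(out, name=f"{arm_pair[0]}_vs_{arm_pair[1]}")


def effective_sample_size(weights: np.ndarray,
                          arms: pd.Series | np.ndarray | None = None
                          ) -> float | pd.Series:
    """Kish effective sample size (sum w)^2 / sum w^2, overall or per arm."""
    w = np.asarray(weights, float)

    def ess(v):
        if not len(v) or (v == 0).all():
            raise ValueError("all-zero weights")
        return float(v.sum() ** 2 / (v ** 2).sum())

    if arms is None:
        return ess(w)
    arms = pd.Series(np.asarray(arms))
    res = {}
    for a, idx in arms.groupby(arms).groups.items():
        v = w[np.asarray(idx)]
        if (v == 0).all():
            raise ValueError(f"all-zero weights in arm {a!r}")
        res[a] = ess(v)
    return pd.Series(res)


def improve_design(cohort: pd.DataFrame, covariates, candidate_terms,
                   threshold: float = 0.10, scheme: str = "overlap",
                   arm_col: str = "arm") -> tuple[list[str], pd.DataFrame]:
    """Greedy iterative design improvement: while any post-weighting |d|
    exceeds the threshold, add the candidate term that most reduces the
    worst imbalance.  Returns (accepted extra terms, final balance table)."""
    accepted: list[str] = []
    pool = list(candidate_terms)
    arms = tuple(sorted(pd.unique(cohort[arm_col])))

    def balance(extra):
        model = fit_propensity(cohort, covariates, tuple(extra), arm_col)
        ws = (overlap_weights(model, cohort[arm_col]) if scheme == "overlap"
              else iptw_weights(model, cohort[arm_col]))
        tabs = [standardized_differences(cohort, ws.weights, (arms[0], a),
                                         covariates, arm_col)
                for a in arms[1:]]
        return pd.concat(tabs, axis=1)

    tab = balance(accepted)
    while tab.abs().to_numpy().max() > threshold and pool:
        best, best_tab, best_max = None, None, tab.abs().to_numpy().max()
        for term in pool:
            try:
                cand = balance(accepted + [term])
            except Exception:
                continue
            if cand.abs().to_numpy().max() < best_max:
                best, best_tab, best_max = term, cand, cand.abs().to_numpy().max()
        if best is None:
            break
        accepted.append(best)
        pool.remove(best)
        tab = best_tab
    return accepted, tab
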