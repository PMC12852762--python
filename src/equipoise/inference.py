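"""Inference: Rubin pooling over multiple imputations, stratified bootstrap
of the full estimation procedure, and BCa confidence intervals.

The sampling scheme mirrors the analysis design: within each imputed
dataset, patients are resampled with replacement within treatment arm
(preserving per-arm sizes), the entire estimator — propensity model,
weights, outcome model, contrast — is re-run on each resample, and the
draws from all imputations are merged into one bootstrap distribution per
measure.  Point estimates are Rubin means over the per-imputation estimates
(log-scale for ratio measures); intervals are bias-corrected and
accelerated percentiles of the merged distribution, with the acceleration
estimated by jackknife over the per-imputation estimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import BootstrapPlan

__all__ = ["rubin_pool", "stratified_resample_indices", "bootstrap_pipeline",
           "bca_interval", "PooledResult"]

#: measures pooled on the log scale (ratios)
LOG_SCALE_PREFIXES = ("rr", "hr")


def _is_log_scale(measure: str) -> bool:
    return measure.split("_")[0] in LOG_SCALE_PREFIXES or \
        measure.startswith(LOG_SCALE_PREFIXES)


def rubin_pool(estimates, log_scale: bool | None = None,
               measure: str = "") -> float:
    """Rubin point estimate: arithmetic mean of the per-imputation
    estimates, on the log scale (geometric mean) for ratio measures.

    Non-finite estimates are excluded with a warning.
    """
    x = np.asarray(list(estimates), float)
    finite = np.isfinite(x)
    if not finite.all():
        warnings.warn(f"excluding {int((~finite).sum())} non-finite "
                      f"estimate(s) from pooling ({measure or 'unnamed'})")
        x = x[finite]
    if len(x) == 0:
        return np.nan
    if log_scale is None:
        log_scale = _is_log_scale(measure)
    if log_scale:
        if (x <= 0).any():
            raise ValueError("ratio estimates must be positive for "
                             "log-scale pooling")
        return float(np.exp(np.mean(np.log(x))))
    return float(np.mean(x))


def stratified_resample_indices(strata: np.ndarray,
                                rng: np.random.Generator) -> np.ndarray:
    """Indices of a with-replacement resample drawn within each stratum,
    preserving every stratum's size."""
    strata = np.asarray(strata)
    out = np.empty(len(strata), int)
    pos = 0
    for s in pd.unique(strata):
        idx = np.flatnonzero(strata == s)
        out[pos:pos + len(idx)] = idx[rng.integers(0, len(idx), len(idx))]
        pos += len(idx)
    return out


def bootstrap_pipeline(datasets: list[pd.DataFrame], plan: BootstrapPlan,
                       estimator, stratify_col: str = "arm",
                       max_failure_rate: float = 0.05) -> pd.DataFrame:
    """Stratified bootstrap of a full estimation procedure over imputed
    datasets.

    ``estimator`` maps a (resampled) dataset to a dict of named estimates
    and must re-run the whole procedure (weights and outcome models), never
    a cached fit.  Returns one row per draw with an ``imputation`` column;
    failed draws are recorded as NaN, and a failure rate above
    ``max_failure_rate`` aborts.
    """
    ss = np.random.SeedSequence(plan.seed)
    streams = ss.spawn(len(datasets))
    rows = []
    failures = 0
    B = plan.samples_per_imputation
    for j, (df, child) in enumerate(zip(datasets, streams)):
        rng = np.random.Generator(np.random.PCG64(child))
        strata = df[stratify_col].to_numpy()
        for b in range(B):
            idx = stratified_resample_indices(strata, rng)
            boot = df.iloc[idx].reset_index(drop=True)
            try:
                est = estimator(boot)
            except Exception:
                failures += 1
                est = {}
            rows.append({"imputation": j, "draw": b, **est})
    out = pd.DataFrame(rows)
    total = len(datasets) * B
    if failures > max_failure_rate * total:
        raise RuntimeError(
            f"bootstrap failure rate {failures}/{total} exceeds "
            f"{max_failure_rate:.0%}")
    out.attrs["failures"] = failures
    return out


@dataclass
class PooledResult:
    measure: str
    point: float
    ci: tuple[float, float]
    n_draws: int
    ci_method: str = "bca"
    z0: float = 0.0
    acceleration: float = 0.0
    degenerate: bool = False


def bca_interval(draws: np.ndarray, point: float, alpha: float = 0.05,
                 block_estimates: np.ndarray | None = None,
                 log_scale: bool = False) -> PooledResult:
    """Bias-corrected and accelerated percentile interval.

    z0 is the normal quantile of the fraction of draws below the point
    estimate; the acceleration comes from a jackknife over the
    per-imputation point estimates when supplied (a = 0 otherwise, the
    bias-corrected-only mode).  Ratio measures are handled on the log scale
    and back-transformed.
    """
    d = np.asarray(draws, float)
    d = d[np.isfinite(d)]
    if len(d) < 100:
        raise ValueError("need at least 100 finite bootstrap draws")
    if log_scale:
        d = np.log(d)
        point_t = np.log(point)
    else:
        point_t = point
    if np.allclose(d, d[0]):
        warnings.warn("degenerate bootstrap distribution: CI collapses to "
                      "the point estimate")
        return PooledResult("", point, (point, point), len(d),
                            degenerate=True)
    frac = np.mean(d < point_t)
    frac = min(max(frac, 1.0 / (len(d) + 1)), len(d) / (len(d) + 1.0))
    z0 = stats.norm.ppf(frac)
    a = 0.0
    if block_estimates is not None and len(block_estimates) >= 3:
        th = np.asarray(block_estimates, float)
        th = np.log(th) if log_scale else th
        th = th[np.isfinite(th)]
        if len(th) >= 3:
            dbar = th.mean() - th
            denom = 6.0 * (np.sum(dbar ** 2) ** 1.5)
            a = float(np.sum(dbar ** 3) / denom) if denom > 0 else 0.0
    zlo, zhi = stats.norm.ppf(alpha / 2), stats.norm.ppf(1 - alpha / 2)

    def level(z):
        return stats.norm.cdf(z0 + (z0 + z) / (1 - a * (z0 + z)))

    lo, hi = np.quantile(d, [level(zlo), level(zhi)])
    if log_scale:
        lo, hi = np.exp(lo), np.exp(hi)
    return PooledResult("", point, (float(lo), float(hi)), len(d),
                        z0=float(z0), acceleration=a)
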