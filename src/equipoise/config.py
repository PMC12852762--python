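"""Configuration objects for the emulation pipeline.

Every tunable of the synthetic cohort generator and of the analysis stages
lives in a dataclass here, so a run is fully determined by (config, seed).
Defaults describe a four-arm antipsychotic initiation cohort of middle-aged
adults with severe mental illness followed monthly for five years, with
moderate confounding by cardiometabolic covariates, a competing risk of
non-cardiovascular death, gradual non-adherence, and MAR missingness in a
subset of baseline covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "ARMS",
    "DDD_MG",
    "HORIZON_MONTHS",
    "MONTH_DAYS",
    "CovariateSpec",
    "SimulationConfig",
    "EligibilityCriteria",
    "ImputationConfig",
    "CensorModelSpec",
    "BootstrapPlan",
    "AnalysisPlan",
    "default_simulation_config",
]

#: Treatment strategies, in canonical order (index arm first).
ARMS: tuple[str, ...] = ("aripiprazole", "olanzapine", "quetiapine", "risperidone")

#: WHO ATC defined daily doses (mg/day), used for olanzapine-equivalent dosing.
DDD_MG: dict[str, float] = {
    "aripiprazole": 15.0,
    "olanzapine": 10.0,
    "quetiapine": 400.0,
    "risperidone": 5.0,
}

#: Follow-up horizon in months and the fixed month length in days.
HORIZON_MONTHS = 60
MONTH_DAYS = 30.4375


@dataclass(frozen=True)
class CovariateSpec:
    """One baseline covariate of the generator.

    kind 'binary' uses params {'p': prevalence}; 'categorical' uses
    {'levels': [...], 'probs': [...]}; 'continuous' uses
    {'dist': 'normal'|'gamma', 'loc'/'scale' or 'shape'/'scale',
    'clip': (lo, hi), 'integer': bool}.  'loc'/'scale' double as the
    standardisation constants used when the covariate enters a linear
    predictor of the generating model.
    """

    name: str
    kind: str
    params: Mapping

    def __post_init__(self):
        if self.kind not in ("binary", "categorical", "continuous"):
            raise ValueError(f"unknown covariate kind {self.kind!r}")
        if self.kind == "categorical":
            probs = np.asarray(self.params["probs"], float)
            if not np.isclose(probs.sum(), 1.0):
                raise ValueError(f"{self.name}: level probabilities must sum to 1")


def _default_covariates() -> tuple[CovariateSpec, ...]:
    return (
        CovariateSpec("age", "continuous",
                      {"dist": "normal", "loc": 55.0, "scale": 12.0,
                       "clip": (40, 99), "integer": True}),
        CovariateSpec("sex", "categorical",
                      {"levels": ["F", "M"], "probs": [0.57, 0.43]}),
        CovariateSpec("ethnicity", "categorical",
                      {"levels": ["White", "Asian", "Black", "Mixed/Other"],
                       "probs": [0.84, 0.065, 0.065, 0.03]}),
        CovariateSpec("smi_diagnosis", "categorical",
                      {"levels": ["bipolar", "other_psychoses", "schizophrenia"],
                       "probs": [0.36, 0.38, 0.26]}),
        CovariateSpec("imd_quintile", "categorical",
                      {"levels": [1, 2, 3, 4, 5],
                       "probs": [0.13, 0.155, 0.19, 0.235, 0.29]}),
        CovariateSpec("diabetes", "binary", {"p": 0.14}),
        CovariateSpec("hypertension", "binary", {"p": 0.28}),
        CovariateSpec("smoking", "categorical",
                      {"levels": ["never", "ex", "current"],
                       "probs": [0.40, 0.15, 0.45]}),
        CovariateSpec("bmi", "continuous",
                      {"dist": "normal", "loc": 28.0, "scale": 6.2,
                       "clip": (15, 60), "integer": False}),
        CovariateSpec("prior_antipsychotic", "binary", {"p": 0.26}),
        CovariateSpec("starting_dose_olz_equiv", "continuous",
                      {"dist": "gamma", "shape": 2.56, "scale": 2.5,
                       "loc": 6.4, "sd": 4.0, "clip": (1.0, 30.0),
                       "integer": False}),
    )


# Treatment-assignment coefficients (softmax scale, per design column).
# Intercepts reproduce the observed arm shares; slopes encode channelling:
# aripiprazole initiators skew younger, heavier, more often diagnosed with
# schizophrenia, diabetic, and of minority ethnicity.
def _default_ps_coefficients() -> dict[str, dict[str, float]]:
    return {
        "aripiprazole": {"_intercept": np.log(0.089), "age": -0.15, "bmi": 0.15,
                         "diabetes": 0.20, "smi_diagnosis=schizophrenia": 0.15,
                         "ethnicity=Asian": 0.20, "ethnicity=Black": 0.20,
                         "ethnicity=Mixed/Other": 0.20},
        "olanzapine": {"_intercept": np.log(0.390), "age": 0.05},
        "quetiapine": {"_intercept": np.log(0.275), "age": 0.10,
                       "hypertension": 0.10},
        "risperidone": {"_intercept": np.log(0.246), "age": 0.15,
                        "prior_antipsychotic": 0.10},
    }


# Additive terms on the logit monthly MACE hazard.  Continuous covariates
# enter standardised by their spec loc/scale; categorical by one-hot with
# the first level as reference.
def _default_hazard_effects() -> dict:
    return {
        "arms": {a: 0.0 for a in ARMS},   # null treatment effect by default
        "covariates": {
            "age": 0.90, "sex=M": 0.30, "diabetes": 0.50, "hypertension": 0.30,
            "smoking=ex": 0.15, "smoking=current": 0.40, "bmi": 0.20,
            "starting_dose_olz_equiv": 0.10,
        },
    }


def _default_adherence() -> dict:
    # Monthly probability of deviating from the initiated strategy, chosen so
    # that ~38-45% of each arm has deviated by month 60, and the split of
    # deviations into switch / addition / discontinuation.
    return {
        "monthly_deviation": {"aripiprazole": 0.0100, "olanzapine": 0.0097,
                              "quetiapine": 0.0080, "risperidone": 0.0091},
        "type_probs": {"switch": 0.40, "addition": 0.20, "discontinuation": 0.40},
        # log-odds shifts on the deviation probability (informative censoring)
        "covariate_log_odds": {"diabetes": 0.30, "age": 0.15},
    }


def _default_missingness() -> dict:
    # MAR: missingness depends only on always-observed fields (age, sex).
    return {
        "ethnicity": {"intercept": -2.45, "predictors": {"age": 0.20}},
        "imd_quintile": {"intercept": -2.95, "predictors": {}},
        "smoking": {"intercept": -1.40, "predictors": {"sex=M": 0.20}},
        "bmi": {"intercept": -1.15, "predictors": {"age": -0.25, "sex=M": 0.30}},
        "starting_dose_olz_equiv": {"intercept": -2.95, "predictors": {}},
    }


@dataclass
class SimulationConfig:
    """Full parameterisation of the synthetic linked-cohort generator."""

    n_patients: int
    seed: int
    arms: tuple[str, ...] = ARMS
    covariate_spec: tuple[CovariateSpec, ...] = field(default_factory=_default_covariates)
    ps_coefficients: dict = field(default_factory=_default_ps_coefficients)
    #: monthly MACE hazard schedule at reference covariates, length 60;
    #: the default yields a ~5.8% marginal five-year MACE risk
    baseline_hazard: np.ndarray = field(
        default_factory=lambda: np.full(HORIZON_MONTHS, 0.0004))
    log_hazard_effects: dict = field(default_factory=_default_hazard_effects)
    #: monthly probability of non-cardiovascular death (scalar or length 60)
    noncv_death_hazard: float | np.ndarray = 0.0018
    adherence_params: dict = field(default_factory=_default_adherence)
    adverse_reaction_prob: float = 0.01
    missingness_spec: dict = field(default_factory=_default_missingness)
    #: split of incident MACE into components; 'fatal_*' carry a death <=28d
    mace_type_probs: dict = field(default_factory=lambda: {
        "mi": 0.22, "stroke": 0.30, "cv_death": 0.33,
        "fatal_mi": 0.07, "fatal_stroke": 0.08})
    #: monthly probability of a new (non-MACE) comorbidity onset episode
    comorbidity_onset_prob: float = 0.004
    recruitment_window: tuple[str, str] = ("2005-01-01", "2014-12-31")
    #: fraction whose SMI diagnosis is only recorded >30 days after index
    late_smi_prob: float = 0.02
    #: fraction whose first prescription is labelled pro re nata
    prn_first_prob: float = 0.01

    def __post_init__(self):
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if self.seed is None:
            raise ValueError("a seed is required (reproducibility contract)")
        if len(set(self.arms)) != 4:
            raise ValueError("arms must contain exactly 4 distinct labels")
        self.baseline_hazard = np.asarray(self.baseline_hazard, float)
        if self.baseline_hazard.shape != (HORIZON_MONTHS,):
            raise ValueError(f"baseline_hazard must have {HORIZON_MONTHS} entries")
        if np.isscalar(self.noncv_death_hazard):
            self.noncv_death_hazard = np.full(HORIZON_MONTHS,
                                              float(self.noncv_death_hazard))
        else:
            self.noncv_death_hazard = np.asarray(self.noncv_death_hazard, float)
        if self.noncv_death_hazard.shape != (HORIZON_MONTHS,):
            raise ValueError(f"noncv_death_hazard must have {HORIZON_MONTHS} entries")
        for arr in (self.baseline_hazard, self.noncv_death_hazard):
            if (arr < 0).any() or (arr > 1).any():
                raise ValueError("hazard probabilities must lie in [0, 1]")
        for p in self.adherence_params["monthly_deviation"].values():
            if not 0 <= p <= 1:
                raise ValueError("monthly deviation probabilities must lie in [0, 1]")
        if not 0 <= self.adverse_reaction_prob <= 1:
            raise ValueError("adverse_reaction_prob must lie in [0, 1]")
        tp = self.mace_type_probs
        if not np.isclose(sum(tp.values()), 1.0):
            raise ValueError("mace_type_probs must sum to 1")

    def with_(self, **kw) -> "SimulationConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kw)


def default_simulation_config(n_patients: int, seed: int, **kw) -> SimulationConfig:
    return SimulationConfig(n_patients=n_patients, seed=seed, **kw)


@dataclass
class EligibilityCriteria:
    """Trial-emulation eligibility rules applied at the index date."""

    age_range: tuple[int, int] = (40, 99)
    registration_lookback_days: int = 183
    recruitment_window: tuple[str, str] = ("2005-01-01", "2014-12-31")
    smi_grace_days_after_index: int = 30
    lai_lookback_days: int = 90
    exclude_pro_re_nata: bool = True
    require_linkage: bool = True
    inclusive_smi: bool = False   # sensitivity variant: SMI code at any time

    def __post_init__(self):
        if self.age_range[0] > self.age_range[1]:
            raise ValueError("age_range must be ordered")
        for d in (self.registration_lookback_days, self.smi_grace_days_after_index,
                  self.lai_lookback_days):
            if d <= 0:
                raise ValueError("day counts must be positive")


@dataclass
class ImputationConfig:
    """Chained-equations imputation settings."""

    m: int = 25
    n_iterations: int = 10
    pmm_donors: int = 5
    seed: int = 0
    predictor_matrix: Mapping[str, Sequence[str]] | None = None

    def __post_init__(self):
        if self.m < 2:
            raise ValueError("m must be at least 2")
        if self.pmm_donors < 1:
            raise ValueError("pmm_donors must be at least 1")


@dataclass
class CensorModelSpec:
    """Specification of the per-protocol censoring model behind IPCW."""

    covariate_set: str = "baseline_only"   # or 'baseline_plus_timevarying'
    stabilised: bool = True
    trim_percentile: float = 99.5
    include_admin_censoring: bool = True

    def __post_init__(self):
        if self.covariate_set not in ("baseline_only", "baseline_plus_timevarying"):
            raise ValueError("unknown covariate_set")
        if not 50 < self.trim_percentile <= 100:
            raise ValueError("trim percentile must lie in (50, 100]")


@dataclass
class BootstrapPlan:
    """Stratified bootstrap layered over multiple imputation."""

    samples_per_imputation: int = 500
    seed: int = 0

    def total_draws(self, m: int) -> int:
        return m * self.samples_per_imputation


@dataclass
class AnalysisPlan:
    """One cell of the analysis grid (estimand x weighting x outcome ...)."""

    estimand: str = "itt"                 # 'itt' | 'pp'
    weighting: str = "overlap"            # 'overlap' | 'iptw'
    outcome: str = "mace"                 # 'mace' | 'mi' | 'stroke' | 'cv_death'
    horizons: tuple[int, ...] = (6, 60)
    censor_weighting: str = "none"        # 'none' | 'baseline' | 'baseline_plus_timevarying'
    eligibility: str = "primary"          # 'primary' | 'inclusive'
    missing: str = "mice"                 # 'mice' | 'complete_case'
    covariates: tuple[str, ...] = (
        "age", "sex", "ethnicity", "smi_diagnosis", "imd_quintile", "diabetes",
        "hypertension", "smoking", "bmi", "prior_antipsychotic",
        "starting_dose_olz_equiv")
    subgroups: tuple[str, ...] = ()
    m_imputations: int = 25
    bootstrap: BootstrapPlan = field(default_factory=BootstrapPlan)
    balance_threshold: float = 0.10
    seed: int = 0

    def __post_init__(self):
        if self.estimand not in ("itt", "pp"):
            raise ValueError("estimand must be 'itt' or 'pp'")
        if self.outcome not in ("mace", "mi", "stroke", "cv_death"):
            raise ValueError("unknown outcome")
        if self.estimand == "pp" and self.outcome != "mace":
            raise ValueError(
                "secondary outcomes are not evaluated under the per-protocol "
                "estimand (low absolute event numbers)")
        if self.censor_weighting != "none" and self.estimand != "pp":
            raise ValueError("censor weighting applies only to the per-protocol estimand")
        if max(self.horizons) > HORIZON_MONTHS:
            raise ValueError("horizon beyond the 60-month follow-up")
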