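import numpy as np
import pandas as pd
import pytest

from equipoise import (AnalysisPlan, apply_missingness, build_cohort,
                       default_simulation_config, generate_cohort)

COVARIATES = list(AnalysisPlan().covariates)


@pytest.fixture(scope="session")
def sim_config():
    """Mid-size default-condition generator config shared across tests."""
    return default_simulation_config(4000, seed=20240901)


@pytest.fixture(scope="session")
def raw_tables(sim_config):
    return apply_missingness(generate_cohort(sim_config), sim_config)


@pytest.fixture(scope="session")
def cohort(raw_tables):
    cohort, _ = build_cohort(raw_tables)
    return cohort


@pytest.fixture(scope="session")
def complete_cohort():
    """A cohort with no missing covariates (missingness switched off)."""
    cfg = default_simulation_config(4000, seed=77, missingness_spec={})
    tables = generate_cohort(cfg)
    cohort, _ = build_cohort(tables)
    return cfg, tables, cohort


def toy_patients(n, index="2010-06-15", **overrides):
    """Hand-editable minimal patients table for eligibility fixtures."""
    idx = pd.Timestamp(index)
    base = dict(
        patient_id=np.arange(1, n + 1),
        birth_year=np.full(n, 1960),
        registration_date=np.full(n, idx - pd.Timedelta(days=400)),
        practice_linkage_eligible=np.ones(n, bool),
        smi_diagnosis_date=np.full(n, idx - pd.Timedelta(days=1000)),
        smi_diagnosis_type=np.full(n, "schizophrenia", object),
        history_mi_stroke_dementia=np.zeros(n, bool),
        deregistration_date=np.full(n, pd.NaT),
        last_collection_date=np.full(n, pd.Timestamp("2021-03-31")),
        sex=np.full(n, "F", object),
        ethnicity=np.full(n, "White", object),
        imd_quintile=np.full(n, 3),
        diabetes=np.zeros(n, int),
        hypertension=np.zeros(n, int),
        smoking=np.full(n, "never", object),
        bmi=np.full(n, 27.0),
        prior_antipsychotic=np.zeros(n, int),
    )
    base.update(overrides)
    return pd.DataFrame(base)


def toy_rx(entries):
    """entries: list of (patient_id, date, drug, dose, prn, lai)."""
    rows = [dict(patient_id=p, date=pd.Timestamp(d), drug=dr,
                 daily_dose_mg=dose, pro_re_nata=prn,
                 long_acting_injectable=lai)
            for p, d, dr, dose, prn, lai in entries]
    cols = ["patient_id", "date", "drug", "daily_dose_mg", "pro_re_nata",
            "long_acting_injectable"]
    return pd.DataFrame(rows, columns=cols)


def empty_episodes():
    return pd.DataFrame(columns=["patient_id", "admission_date",
                                 "primary_icd10"])


def empty_deaths():
    return pd.DataFrame(columns=["patient_id", "date",
                                 "underlying_cause_icd10"])


def empty_adverse():
    return pd.DataFrame(columns=["patient_id", "date", "drug"])
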