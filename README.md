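# equipoise

Target-trial emulation of multi-arm treatment strategies on EHR-like data,
built around the question: *does initiating aripiprazole rather than
olanzapine, quetiapine, or risperidone change the five-year risk of a major
adverse cardiovascular event (MACE) in adults with severe mental illness?*

The package is for epidemiologists and biostatisticians who want a tested,
reusable implementation of the full analysis chain for multi-arm
observational emulations:

- **cohort construction** from linked patient / prescription / hospital
  episode / death-registration tables (eligibility at the index
  prescription, ICD-10 outcome rules with a 28-day fatality rule,
  intention-to-treat and per-protocol follow-up);
- **generalised overlap weighting** for four arms,
  `w_i = (1/p_{i,Z_i}) / Σ_k (1/p_{ik})` from a multinomial propensity
  model — targeting the population at clinical equipoise — with IPTW,
  standardised-difference balance checks and Kish effective sample sizes;
- **discrete-time pooled logistic regression** on person-months,
  `logit h(t, arm) = α + g(t) + Σ_k β_k arm_k + Σ_k γ_k arm_k·t`, giving
  marginal cumulative incidence `R(t) = 1 − Π_u (1 − h(u))`, risk
  differences/ratios, and hazard ratios (discrete and Cox with robust SEs);
- **inverse-probability-of-censoring weights** for the per-protocol
  estimand, stabilised and winsorised, with an optional time-varying
  comorbidity-count term;
- **multiple imputation by chained equations** (predictive mean matching +
  multinomial draws) combined with a **treatment-stratified bootstrap of
  the whole procedure** and **BCa confidence intervals**.

Because the linked health records such studies use are access-controlled,
the package includes a first-class synthetic cohort generator
(`equipoise.simulate`) with confounded treatment assignment, monthly event
hazards, competing non-cardiovascular death, adherence processes and MAR
missingness — and an exact ground-truth oracle (`true_marginal_risk`) that
every estimation stage is tested against. See `docs/methods.md` for the
model, its assumptions, and what passing tests do and do not show.

## Worked example

```python
import numpy as np
from equipoise import (AnalysisPlan, BootstrapPlan,
                       default_simulation_config, run_emulation)

cfg = default_simulation_config(n_patients=6000, seed=1)   # null effects
plan = AnalysisPlan(m_imputations=5,
                    bootstrap=BootstrapPlan(samples_per_imputation=100),
                    seed=42)
bundle = run_emulation(cfg, plan)

r = bundle["results"]["rr_60m_risperidone"]
print(f"5-y MACE RR, aripiprazole vs risperidone: "
      f"{r['point']:.2f} (95% CI {r['ci'][0]:.2f}, {r['ci'][1]:.2f})")
print(f"max mean standardised difference: "
      f"{bundle['max_mean_std_difference']:.3f}")
print(f"weighted ESS: {bundle['ess_total']:.0f} of {bundle['n_cohort']}")
```

prints:

```
5-y MACE RR, aripiprazole vs risperidone: 0.76 (95% CI 0.41, 1.14)
max mean standardised difference: 0.026
weighted ESS: 5644 of 5829
```

The risk ratio's interval covers 1 — the generator's default treatment
effects are null — the post-weighting imbalance is far below the 0.10
threshold, and overlap weighting retains ~95% of the information in this
well-overlapping cohort. The same entry point runs the per-protocol
estimand with censor weighting (`estimand="pp"`,
`censor_weighting="baseline_plus_timevarying"`), IPTW, complete-case and
inclusive-eligibility variants; `sensitivity_suite` runs the whole grid.

A CLI mirrors the stages:

```bash
equipoise simulate --n 6000 --seed 1 --out tables/
equipoise build-cohort --tables tables/ --out cohort/
equipoise run --n 6000 --seed 1 --plan plan.yaml --out results/
```

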