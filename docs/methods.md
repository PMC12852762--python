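# Methods

`equipoise` implements an observational emulation of a four-arm pragmatic
trial of antipsychotic initiation strategies (aripiprazole, olanzapine,
quetiapine, risperidone) in adults with severe mental illness (SMI), with
the five-year risk of a major adverse cardiovascular event (MACE) as the
outcome. Because the real linked primary-care / hospital / death-registry
data such a study uses are access-controlled, the package ships a synthetic
linked-cohort generator with known ground truth; every estimation stage is
validated against that truth.

## The estimand and the analysis chain

Follow-up runs on a discrete monthly grid: 60 intervals of 30.4375 days,
with month index `floor(days since index / 30.4375) + 1`. An event recorded
in a month counts before that month's censoring (event-first tie-break, the
conservative discrete-time convention).

1. **Cohort construction.** Index date is the first prescription of a study
   antipsychotic inside the 2005-2014 recruitment window; patients are
   eligible once. Exclusions, applied sequentially with a flow tally: index
   outside the window; age outside 40-99; under 183 days of practice
   registration; prior MI/stroke/dementia; not linkage-eligible; a second
   study antipsychotic co-prescribed at index; a long-acting injectable in
   the prior 90 days; a pro-re-nata first prescription; no SMI diagnosis by
   index + 30 days (an *inclusive* variant accepts an SMI code at any
   time). MACE = hospital episode with primary ICD-10 I21\* (MI) or
   I60\*-I64\* (stroke), or death with an underlying cause in the
   circulatory chapter; any death within 28 days of an MI/stroke episode is
   recoded as cardiovascular death. Intention-to-treat (ITT) follow-up is
   censored at the earlier of non-cardiovascular death and 60 months;
   component outcomes censor at component (not composite) incidence.
   Per-protocol (PP) follow-up additionally censors at antipsychotic
   switch, addition, discontinuation (183 days after the last
   prescription), deregistration, or the practice's last collection date —
   except when an adverse-reaction code for the original drug appears
   within 30 days of the change (treatment change is then
   strategy-consistent, and the patient is exempt from further
   deviation-based censoring). Doses are expressed as olanzapine
   equivalents via WHO defined daily doses (aripiprazole 15, olanzapine 10,
   quetiapine 400, risperidone 5 mg/day).

2. **Missing data.** MICE with predictive mean matching (type-1 PMM, 5
   donors) for continuous covariates and a multinomial-logistic draw for
   categorical ones; 10 cycles; m = 25 datasets by default. The treatment
   arm, the event indicator and log follow-up time always enter the
   predictor matrix (survival-aware imputation). The categorical engine
   draws from fitted class probabilities without a posterior coefficient
   draw — slightly under-dispersed relative to fully Bayesian imputation,
   acceptable here because interval estimation comes from the bootstrap,
   not from Rubin's variance rules. A complete-case variant exists for
   sensitivity analysis.

3. **Weighting.** Propensities from a maximum-likelihood multinomial
   logistic model (main effects of the 11 baseline covariates; candidate
   nonlinear/interaction terms can be added greedily while any
   standardised difference exceeds 0.10). Generalised overlap weights
   `w_i = (1/p_{i,Z_i}) / Σ_k (1/p_{ik})` target the population at
   clinical equipoise and are bounded by construction. IPTW (stabilised by
   arm prevalence, winsorised at the 99th percentile — capping, not
   deletion) is the sensitivity scheme. Balance is judged by weighted
   standardised differences with *unweighted* pooled SDs (so weighting
   moves only the numerator), averaged over imputed datasets, against the
   0.10 threshold; the pipeline refuses to report causal contrasts when
   the threshold is breached. Kish effective sample sizes
   `(Σw)²/Σw²` are reported per arm.

4. **Outcome models.** A weighted pooled logistic regression on
   person-months: `logit h(t, arm) = α + g(t) + Σ β_k arm_k + Σ γ_k
   arm_k·t`, with g(t) linear by default (restricted cubic spline
   available; knots 6, 18, 30, 42, 54 months). Confounding is carried
   entirely by the weights, so predicted risks `R(t) = 1 − Π(1 − h)` are
   marginal in the weighted population; risk differences (per 1000) and
   ratios are read from R(6) and R(60) of the same fitted model. Hazard
   ratios come from the no-interaction pooled logistic (rare-event
   approximation) and from a lifelines Cox model with robust SEs (event
   times at mid-month on the day scale). Effect modification is tested by
   robust Wald chi-squares on arm × modifier blocks in the weighted Cox
   model; age and dose enter as continuous, ethnicity as White/other.

5. **Censor weighting (PP).** Monthly censoring models — a numerator with
   arm and time only, a denominator adding baseline covariates and
   optionally a time-varying cumulative comorbidity count (distinct
   non-MACE diagnosis categories to date) — yield stabilised IPCW as a
   lagged cumulative product of uncensored-probability ratios: weights are
   1 in month 1 and accumulate through positive monthly ratios only.
   Weights are winsorised at the 99.5th percentile and multiplied into the
   overlap weights.

6. **Inference.** Within each imputed dataset, patients are resampled with
   replacement within arm (preserving arm sizes) and the whole procedure —
   propensity fit, weights, censor weights where applicable, outcome model,
   contrast — is re-run per draw (500/dataset by default; 100 in reduced
   mode). Draws merge across imputations into one distribution per
   measure. Points are Rubin means of the per-imputation estimates
   (log-scale for ratios); intervals are BCa percentiles with z0 from the
   fraction of draws below the point and acceleration from a jackknife
   over the per-imputation estimates (a = 0 when fewer than three blocks).
   Cox hazard ratios are reported with robust-SE inference rather than
   bootstrapped: the computational cost of bootstrapping the partial
   likelihood is disproportionate, and the pooled-logistic HR carries the
   bootstrap interval.

## The synthetic cohort

The generator emulates linked UK-style records: a patients table with
demographics and comorbidities, monthly primary-care prescription issues,
hospital episodes with ICD-10 primary diagnoses, death registrations with
an underlying cause, and rare adverse-reaction codes. Defaults describe the
study conditions: eleven baseline covariates with marginal distributions
matching the published cohort (median age ~52, 57% female, 84% White, 26%
schizophrenia, BMI ~28 (SD 6), olanzapine-equivalent starting dose ~6.4 mg
(SD 4)); treatment assignment by softmax on covariates with channelling of
younger, heavier, diabetic and minority-ethnicity patients toward
aripiprazole and arm shares ≈ 9/39/27/25%; a constant baseline monthly MACE
hazard of 0.0004 with log-linear covariate effects, yielding ≈5.8%
five-year marginal risk; a competing non-cardiovascular death hazard of
0.0018/month (≈10% by five years); monthly strategy-deviation
probabilities tuned so 38-45% are non-adherent by five years, split
40/20/40 into switch/addition/discontinuation, with optional covariate
log-odds (informative censoring); adverse-reaction codes on 1% of
deviations; MAR missingness (logistic in age and sex) in ethnicity, IMD
quintile, smoking, BMI and dose, between ~5% and ~26% per variable; and
null treatment effects unless configured otherwise. Every random component
draws from its own named stream split from the master seed, laid out
patient-major, so regeneration is byte-identical and enlarging the cohort
never perturbs earlier patients.

What the generator does *not* emulate: real clinical coding beyond the
ICD-10 stems the outcome rules need, duplicate records across primary-care
systems, seasonality or calendar trends in hazards, dose titration, or
hazard changes after strategy deviation (deviation affects selection, not
biology — which is exactly what makes the IPCW recovery checks sharp).
Passing tests therefore demonstrate the estimators' correctness under the
assumed data-generating model, not robustness to coding noise or model
misspecification in real data.

## Numerical choices

The binomial-logistic and multinomial-softmax solvers are damped Newton
iterations with analytic Hessians, converging at gradient norm < 1e-6
(≤200 iterations); a converged coefficient above 15 in absolute value, or
a runaway during iteration, raises a perfect-separation error naming the
column. The pooled-logistic fit collapses person-month rows with identical
design vectors into weighted binomial counts — an exact reduction of the
weighted likelihood — so a fit costs the same at n = 2,000 and n = 200,000
person-months; the bootstrap path aggregates (arm × month) counts directly
from per-patient follow-up without materialising rows. Fits are invariant
to rescaling all weights by a constant (checked by test). Degenerate
inputs: zero-variance covariates give standardised difference 0; an arm
with no censoring events gets censor weights 1 with a warning; a
degenerate bootstrap distribution collapses the CI to the point with a
flag; non-finite per-imputation estimates are excluded from pooling with a
count.

## Problem sizes used by the test suite and acceptance script

Formula oracles run at 10,000 random propensity vectors and 100 random
hazard models (tolerance 1e-12). Parameter recovery runs two confounded
scenarios (true risk ratio 1.0 and 0.8) at n = 20,000 with 100-draw
bootstrap SEs. The size check runs 200 null replicates at n = 2,500 with
110 bootstrap draws each (band: 2-9% of 95% CIs excluding the null). IPCW
recovery runs at n = 8,000 with 60-draw SEs. The acceptance script runs
the full ITT and per-protocol emulations at n = 6,000 with m = 5
imputations and 100 (ITT) / 50 (PP) bootstrap samples per imputation, and
the recovery check at n = 12,000. These sizes are scaled-down study
conditions chosen to keep single-CPU runs short while leaving the
Monte-Carlo bands meaningful.

## Known limitations

- The per-protocol censoring model assumes a logistic-in-covariates,
  linear-in-month censoring hazard; the generator's discontinuation censor
  (deviation + ~6 months) makes that mildly misspecified, visible as a
  small residual IPCW bias well inside the Monte-Carlo bands at test sizes.
- BCa acceleration over an MI-bootstrap ensemble has no canonical
  definition; the jackknife over per-imputation estimates is a cheap,
  honest choice, and a = 0 (bias-corrected-only) is the documented
  fallback.
- The switch-vs-addition label depends on the 183-day "still active" rule;
  both reasons censor identically, so only the reason breakdown is
  affected.
- `mice` here is a two-engine implementation, not a general framework: no
  passive imputation, no custom engines per variable, diagnostics limited
  to per-iteration chain means (`df.attrs["mice_trace"]`).
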