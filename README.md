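# vaxadapt

Simulation and analysis toolkit for a **Bayesian adaptive factorial trial
of SMS vaccination reminders**: 12 reminder arms — four content framings
(neutral, personal benefit, personal risk, pro-social) crossed with three
send timings (14 days before the due date, on the due date, 7 days after) —
against a no-reminder control, in a primary-care population of parents with
children on the routine schedule (2, 4, 6, 12, 18, 48 months).

It is written for trial statisticians and methods researchers who want to
study or re-run this class of design end to end: synthetic occasion-level
data with the structure the analysis assumes, mass-weighted urn
randomisation with sibling consistency, reminder eligibility/withholding
and endpoint rules, the five pre-specified Bayesian logistic models,
response-adaptive reallocation with a control-discontinuation rule, and
replicate-trial operating characteristics.

## The model

The primary endpoint is on-time vaccination — receipt within [−14, +28]
days of the due date — analysed on each parent's *index occasion* (first
SMS-eligible occasion after randomisation). The primary model is a Bayesian
logistic regression

  logit P(on time) = β₀ + β_f + γ_t + δ_ft + α_s + τ_e + u_c,

with framing f, timing t, their interaction, schedule point s, 4-week
calendar epoch e, and clinic random intercept u_c ~ N(0, σ²_c); reduced
structures drop the interaction, keep only framing, only timing, or pool
everything into one any-reminder effect θ. Allocation adapts at interim
analyses (first at 1,500 completed index occasions, then every 500) with
reminder-arm weights ∝ √(Pr(best)·Var(log-odds)/n), control fixed at 1/5
until the pooled or any single arm's Pr(OR > 1) crosses a null-calibrated
superiority threshold, after which control allocation stops for good.

See `docs/methods.md` for assumptions, priors, engines and limitations.

## Worked example

```python
import numpy as np
from vaxadapt import (ScenarioConfig, generate_population, init_allocation,
                      assign_arm, assign_and_simulate, mark_index_occasions,
                      OnTimeLogisticModel)

cfg = ScenarioConfig(n_parents_max=4000, seed=11).with_uniform_or(1.5)
rng = np.random.default_rng(11)
pop = generate_population(cfg, rng)
urn = init_allocation()
arm_of = {p.parent_id: assign_arm(urn, str(p.parent_id), rng) for p in pop.parents}
occ = mark_index_occasions(assign_and_simulate(pop, arm_of, cfg, rng))

res = OnTimeLogisticModel.from_dataframe(occ, structure="shared").fit(
    engine="laplace", n_draws=10_000, seed=1)
print(res.summary())
```

```
Bayesian logistic model of on-time vaccination
======================================================
structure: shared           unit: index
engine:    laplace          draws: 10000
rows: 4000   clinics: 20   converged: True
sigma_clinic: 0.096
------------------------------------------------------
arm                median OR           95% CrI  Pr(>1)
neutral@day-14          1.43      (1.23, 1.68)    1.00
...
pooled Pr(OR>1): 1.000
```

The data were generated with every reminder arm at a true odds ratio of
1.5 against a 45% baseline; the shared model recovers a pooled OR of 1.43
(95% CrI 1.23–1.68) with posterior probability ≈1 that reminders help, and
`res.marginal_difference()` converts this to an absolute increase of about
8.5 percentage points (95% CrI 4.8–12.4) in on-time vaccination for a
typical clinic at the latest calendar epoch.

One full adaptive trial, and design-level properties over replicates:

```python
from vaxadapt import run_virtual_trial, estimate_oc, calibrate_threshold, DecisionThresholds

cal = calibrate_threshold(ScenarioConfig(), n_replicates=200, base_seed=1)
oc = estimate_oc(ScenarioConfig().with_uniform_or(1.5),
                 DecisionThresholds(cal.threshold), n_replicates=200, base_seed=2)
print(cal.threshold, oc.declare_rate)
```

A `vaxadapt` command-line interface wraps the same functions
(`simulate`, `run-trial`, `oc`, `calibrate`, `analyse`, `report`).

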